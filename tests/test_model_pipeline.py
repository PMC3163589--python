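import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from seqibd import (
    IsolationByDistance,
    PipelineConfig,
    SeqSiteMap,
    SiteTable,
    SyntheticConfig,
    ValidationError,
    generate_ibd_dataset,
    run_pipeline,
    summarize_pairs,
    write_alignment,
)
from seqibd.cli import main as cli_main
from seqibd.simulate import write_dataset

from conftest import make_dm, random_dm


@pytest.fixture(scope="module")
def synthetic_files(tmp_path_factory):
    """12 sites x 4 sequences, written in the pipeline's input formats."""
    out = tmp_path_factory.mktemp("dataset")
    cfg = SyntheticConfig(n_sites=12, seqs_per_site=4, ibd_strength=0.8, seed=21)
    aln, seq_map, sites, truth = generate_ibd_dataset(cfg)
    return write_dataset(out, aln, seq_map, sites, truth)


def pipeline_config(paths, out_dir, **overrides) -> PipelineConfig:
    kwargs = dict(
        alignment_path=str(paths["alignment"]),
        site_table_path=str(paths["sites"]),
        seq_site_map_path=str(paths["seq_map"]),
        output_dir=str(out_dir),
        n_permutations=99,
        seed=13,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


class TestModel:
    def test_pairs_table_covers_all_pairs(self, synthetic_files):
        model = IsolationByDistance.from_files(
            synthetic_files["alignment"],
            synthetic_files["sites"],
            synthetic_files["seq_map"],
        )
        res = model.fit(n_permutations=49, seed=1)
        n = len(model.d_genetic)
        assert len(res.pairs_table()) == n * (n - 1) // 2

    def test_provenance_reports_retained_columns(self, synthetic_files):
        model = IsolationByDistance.from_files(
            synthetic_files["alignment"],
            synthetic_files["sites"],
            synthetic_files["seq_map"],
        )
        prov = model.provenance
        assert prov["n_columns_retained"] <= prov["n_columns_input"]
        assert prov["n_sequences"] == 48

    def test_summary_mentions_key_quantities(self, synthetic_files):
        model = IsolationByDistance.from_files(
            synthetic_files["alignment"],
            synthetic_files["sites"],
            synthetic_files["seq_map"],
        )
        res = model.fit(n_permutations=49, seed=1)
        text = res.summary()
        assert "r_M" in text and "Sturge" in text and "corrected alpha" in text

    def test_mismatched_ids_rejected(self, rng):
        a = random_dm(5, rng)
        b = make_dm(np.asarray(random_dm(5, rng).values),
                    ids=[f"other{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            IsolationByDistance(a, b)

    def test_exclude_same_site_pairs_shrinks_mask(self, synthetic_files):
        model = IsolationByDistance.from_files(
            synthetic_files["alignment"],
            synthetic_files["sites"],
            synthetic_files["seq_map"],
        )
        res_all = model.fit(n_permutations=49, seed=1)
        res_between = model.fit(n_permutations=49, seed=1,
                                include_same_site_pairs=False)
        assert (res_between.global_mantel.n_pairs_used
                < res_all.global_mantel.n_pairs_used)


class TestPipeline:
    def test_correlogram_row_count_follows_sturges(self, synthetic_files, tmp_path):
        # 48 sequences -> 1128 pairs -> ceil(1 + log2 1128) = 12 classes
        results = run_pipeline(pipeline_config(synthetic_files, tmp_path / "o"))
        assert results.correlogram.k == 12
        table = pd.read_csv(tmp_path / "o" / "correlogram.tsv", sep="\t", comment="#")
        assert len(table) == 12

    def test_outputs_byte_identical_across_reruns(self, synthetic_files, tmp_path):
        run_pipeline(pipeline_config(synthetic_files, tmp_path / "r1"))
        run_pipeline(pipeline_config(synthetic_files, tmp_path / "r2"))
        for name in [
            "genetic_distances.tsv",
            "geographic_distances.tsv",
            "global_mantel.tsv",
            "correlogram.tsv",
            "pairs.tsv",
            "pairs_binned.tsv",
        ]:
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()

    def test_single_site_geography_is_untestable_not_fatal(self, tmp_path):
        cfg = SyntheticConfig(n_sites=4, seqs_per_site=2, seed=2)
        aln, _, _, _ = generate_ibd_dataset(cfg)
        write_alignment(aln, tmp_path / "aln.fasta")
        SiteTable.from_records([("only", 10.0, 10.0)]).to_csv(tmp_path / "sites.csv")
        SeqSiteMap.from_mapping({sid: "only" for sid in aln.ids}).to_csv(
            tmp_path / "map.csv"
        )
        cfg = PipelineConfig(
            alignment_path=str(tmp_path / "aln.fasta"),
            site_table_path=str(tmp_path / "sites.csv"),
            seq_site_map_path=str(tmp_path / "map.csv"),
            output_dir=str(tmp_path / "out"),
            n_permutations=49,
            seed=3,
        )
        results = run_pipeline(cfg)
        assert not results.global_mantel.testable
        summary = json.loads((tmp_path / "out" / "run_summary.json").read_text())
        assert summary["global_mantel"]["testable"] is False

    def test_significance_flags_recompute_from_outputs(self, synthetic_files, tmp_path):
        run_pipeline(pipeline_config(synthetic_files, tmp_path / "o"))
        text = (tmp_path / "o" / "correlogram.tsv").read_text()
        corrected = float(
            next(l for l in text.splitlines() if l.startswith("# corrected_alpha"))
            .split("=")[1]
        )
        table = pd.read_csv(tmp_path / "o" / "correlogram.tsv", sep="\t", comment="#")
        recomputed = table["testable"] & (table["p_value"] < corrected)
        assert list(recomputed.fillna(False)) == list(table["significant"])


class TestSummarizePairs:
    def test_distinct_points_all_count_one(self, rng):
        g = random_dm(6, rng, scale=0.04)
        geo = make_dm(np.asarray(random_dm(6, rng, scale=20000).values), ids=g.ids)
        table = summarize_pairs(g, geo)
        assert (table["count"] == 1).all()
        assert (table["size_bin"] == "1").all()

    def test_repeated_point_binned_3_to_4(self):
        # 4 identical (geo, genetic) pairs land in the 3-4 size bin
        geo_vals = np.zeros((5, 5))
        geo_vals[0, 1:] = geo_vals[1:, 0] = 1000.0
        gen_vals = np.zeros((5, 5))
        gen_vals[0, 1:] = gen_vals[1:, 0] = 0.01
        gen = make_dm(gen_vals)
        geo = make_dm(geo_vals, ids=gen.ids)
        table = summarize_pairs(gen, geo)
        point = table[(table["geo_km"] == 1000.0) & (table["p_distance"] == 0.01)]
        assert point["count"].item() == 4
        assert point["size_bin"].item() == "3-4"

    def test_counts_conserved(self, rng):
        g = random_dm(10, rng, scale=0.04)
        geo = make_dm(np.asarray(random_dm(10, rng, scale=20000).values), ids=g.ids)
        table = summarize_pairs(g, geo)
        assert table["count"].sum() == g.n_pairs

    def test_mismatched_ids_rejected(self, rng):
        g = random_dm(5, rng)
        geo = make_dm(np.asarray(random_dm(5, rng).values),
                      ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            summarize_pairs(g, geo)


class TestCLI:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        data_dir = tmp_path / "data"
        sim = runner.invoke(
            cli_main,
            ["simulate", "--out", str(data_dir), "--n-sites", "8",
             "--seqs-per-site", "3", "--ibd-strength", "0.9", "--seed", "5"],
        )
        assert sim.exit_code == 0, sim.output
        assert (data_dir / "alignment.fasta").exists()
        out_dir = tmp_path / "results"
        run = runner.invoke(
            cli_main,
            ["run",
             "--alignment", str(data_dir / "alignment.fasta"),
             "--sites", str(data_dir / "sites.csv"),
             "--map", str(data_dir / "seq_map.csv"),
             "--out", str(out_dir),
             "--permutations", "99", "--seed", "5"],
        )
        assert run.exit_code == 0, run.output
        assert "Global Mantel test" in run.output
        assert (out_dir / "correlogram.tsv").exists()
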
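# Methods

## The model

The question is whether genetic divergence between homologous sequences
increases with the geographic separation of their sampling sites —
isolation by distance (IBD). The package treats the data as two
symmetric distance matrices over the same sequence ids and asks two
questions of them: globally, are the matrices positively correlated
(Mantel permutation test); and locally, at which spatial scales does the
correlation hold (Mantel correlogram over distance classes)?

### Genetic distances

Uncorrected p-distance: the proportion of compared alignment positions
at which two sequences differ, with no multiple-hit correction. At the
few-percent divergences typical of a within-genus 16S data set the
multiple-hit correction is negligible, and p-distance is what alignment
editors export. Comparison uses pairwise deletion — a position counts
for a pair only if both sequences carry an unambiguous base (A/C/G/T)
there; gaps and IUPAC ambiguity codes never count as matches or
mismatches. The per-pair count of comparable positions is kept on the
matrix (`counts`) for provenance. Complete deletion (dropping any column
with a gap anywhere) is the main alternative; pairwise deletion was
chosen because it uses strictly more data and matches common export
behaviour, and the choice is documented rather than switchable.

Before distances are computed the alignment passes a base-frequency
column filter: a column is retained iff its modal unambiguous base, as a
fraction of the column's non-gap non-ambiguous characters, is at least
the threshold (default 0.30, boundary inclusive — positions *below* 30%
are excluded). This is the conserved-position mask alignment curators
apply before exporting distances; a `count_gaps` switch puts gaps in the
denominator for sensitivity analysis. An entropy-based
hypervariable-column selector (`select_hypervariable`) retains the top
fraction of columns by Shannon entropy over unambiguous bases, ties
broken toward the lower column index — a coordinate-free stand-in for
restricting to the 16S hypervariable regions when the alignment's region
coordinates are unknown.

### Geographic distances

Great-circle distances on a sphere, haversine formula (numerically
stable near zero separation, unlike the spherical law of cosines). The
default radius 6378.388 km is the international-ellipsoid equatorial
radius used by the classical geostatistics great-circle routines; with
it the two polar glacier sites of the bundled survey geometry come out
18,830–18,838 km apart, matching the published figures; a 6371 km mean
radius would give ≈18,810 km. The radius is a parameter. Sequences
sampled at the same site get distance 0. Ellipsoidal geodesics are out
of scope — sub-0.5% differences are far below the resolution of the
analysis.

### Global Mantel test

r_M is the Pearson correlation between the two matrices' upper-triangle
vectors. The permutation null relabels one matrix (rows and columns
jointly) and recomputes r_M; the p-value uses the add-one convention
p = (1 + #{permuted r at least as extreme}) / (1 + n_permutations), so
p ≥ 1/(n_permutations+1) and can never be zero. Default 1000
permutations, one-sided "greater" tail, because the IBD hypothesis is a
positive association; "less" and "two-sided" are flags. An exact
enumeration variant (`mantel_exact`, ≤ 8 ids, all n! relabelings
including the identity) serves as the test oracle for the Monte-Carlo
path. Same-site (zero-geographic-distance) pairs are included in the
global test by default; `include_same_site_pairs=False` drops them.

With a `pair_mask`, r_M is computed over a fixed set of matrix
*positions*; labels move under permutation while mask positions do not.
This positional convention is what makes per-class tests well defined.
If a masked vector has zero variance, the statistic signals
"untestable" (a distinct condition, not a numeric error). During
permutation a relabelled masked vector can occasionally lose all
variance; such permuted statistics are scored 0 (no association) in the
tail count — a convention that matters only in pathological masks and
is noted here for reproducibility.

### Mantel correlogram

Sturge's rule k = ⌈1 + log₂ N⌉ on the number N of sequence pairs sets
the class count (at N = 1378, k = 12). The N pairs, sorted by
geographic distance (stable; ties broken by row then column index), are
cut into equal-count classes: the first k−1 classes take ⌈N/k⌉ pairs
each, the last takes the remainder (115 × 11 + 113 at N = 1378 — equal
counts are arithmetically impossible there, and ceiling-first sizing
keeps all but the final class at the nominal size). Equal counts give
every per-class test the same statistical power. Class bounds are the
observed min/max geographic distances among member pairs; the plotted
abscissa is the midpoint.

Per-class test, default (`restricted`): the Mantel correlation between
genetic and geographic distance restricted to the class's pairs, with
the class's positions as a fixed mask. A class with no geographic
variation — typically a shortest class made entirely of same-site
pairs — is untestable and reported with null r_M and p rather than
dropped. Alternative (`membership`): the classical indicator-matrix
statistic, the sign-flipped correlation between genetic distance and
class membership over all pairs, so that genetically-similar pairs
concentrated in a class give positive r_M. Under a monotone
distance–divergence relation the restricted variant shows positive r in
short classes and noise-dominated r in the longest (within-class range
shrinks relative to noise), while the membership variant traces the
canonical positive-to-negative correlogram shape; the membership
variant is the one to use when that shape is the object of interest.

Per-class significance is judged against α/k unrounded (0.05/12 =
0.004166…, displayed as 0.004); Bonferroni because the k class tests
are a simultaneous family. One user seed drives all classes through
independent substreams (the class index is mixed into the seed
sequence), so class i's p-value does not depend on k.

## Synthetic data

The generator emulates the shape of a global cryosphere 16S survey:
sites uniform on the sphere (longitude uniform, sine of latitude
uniform — separations up to ~19,000 km), a handful of sequences per
site, 1.3 kb columns, and a small total divergence range. Defaults:
15 sites × 4 sequences, seq_length 1300, max_p_distance 0.04 (matching
the few-percent within-genus range), ibd_strength 0.5, noise_sd 0.005
(~⅛ of the divergence range). The defaults were fixed once as the
realistic study shape; analyses in the tests set `ibd_strength` to the
extremes (0 for the null, 1 for maximal signal) explicitly.

Target expected p-distance for a pair:

    t_ij = max_p · [w · geo_ij / max(geo) + (1 − w) · u_ij] + ε_ij

with w = ibd_strength, u_ij ~ U(0,1) i.i.d. per pair, ε_ij ~ N(0,
noise_sd²), clipped to [0, max_p]. The clipping introduces a small bias
at the boundaries, accepted to keep targets valid proportions.

Realization: an arbitrary pairwise target matrix is generally not
realizable by any single set of sequences (pairwise divergences of
sequences are approximately tree-additive, and spherical distances are
not). A star phylogeny is the simplest realization but provably erases
the signal here: on a sphere every point's mean distance to uniform
points is the same (πR/2), so the least-squares star fit q_i + q_j ≈
t_ij is nearly constant and the realized matrix decorrelates from
geography. The generator therefore fits a neighbor-joining tree to the
target matrix (negative branch lengths clipped to zero), takes each
branch length as a per-branch substitution probability, and evolves a
uniform-random root sequence down the tree, each position independently
substituting to a uniformly chosen different base. Realized pairwise
mismatch counts are then binomial around the tree-implied expectations,
and the function returns those exact expectations as ground truth: each
branch is a Jukes-Cantor channel with mismatch eigenvalue (1 − 4b/3),
channels compose along paths, so E[p_ij] = ¾(1 − ∏path(1 − 4b/3)).
Regressing realized on expected distances has slope 1 in expectation
(the generator's calibration property; per-replicate scatter is large
because pairs share branches, so the test averages replicates).

What the generator does *not* emulate: coalescent or stepping-stone
demography, indels, rate heterogeneity across sites, sequencing error
profiles, or uneven global site placement. Passing tests therefore show
the statistical machinery behaves correctly on data with a known,
controllable spatial signal — not that any particular real survey has
that signal.

## Numerical and design notes

- Distance matrices are validated symmetric, hollow and nonnegative at
  construction and exactly symmetrized; ids are ordered and unique.
- Haversine's asin argument is clipped to [0, 1] against rounding.
- Sturge's count uses exact ceil on log₂; `equal_count_classes` refuses
  a k whose ceiling-first sizing would empty the final class.
- Permutations use numpy's PCG64 generator; every stochastic entry
  point takes a seed and records it in its result object, and rerunning
  a pipeline with the same config is byte-identical.
- Problem sizes in the test suite (15 sites × 4–5 sequences, 200 null
  replicates at 999 permutations, 50 power replicates, 50,000
  permutations against exhaustive enumeration at 5–6 ids) were chosen
  to give tight binomial error bars on the calibration checks while the
  whole suite stays fast on one CPU.

## Limitations

- Mantel-type tests have known limitations (sensitivity to spatial
  autocorrelation structure, low power against some alternatives);
  partial Mantel tests and rank variants are deliberately out of scope.
- p-distance without correction understates divergence beyond a few
  percent; do not use for deeply diverged data.
- The equal-count classing is one of several correlogram conventions
  (equal-width classes, progressive Bonferroni and FDR corrections are
  not implemented).
- The bundled survey geometry ships coordinates and accession ids only;
  reproducing the published sequence analysis requires an external
  fetch-and-align step, and the published sequence subset is ambiguous
  (1378 pairs imply 53 sequences; 55 accessions are listed), so
  published statistics are soft targets for that exercise.
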
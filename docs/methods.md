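# Methods

## Model

The annotator treats function prediction as a rank-enrichment problem in
an embedding space of local protein structure. Its central assumption is
that residues performing the same catalytic role sit in similar atomic
microenvironments, so their embeddings are mutually close, while residues
of unrelated function are near-orthogonal in high dimension. Given that
assumption, a query protein carrying function *F* pulls the database
residues of *F* toward the top of a list ranked by max cosine similarity
to the query, and a weighted Kolmogorov–Smirnov running sum detects the
enrichment.

The statistic follows the preranked gene-set enrichment formulation:
walking the ranked database, the running sum *S* gains
|r_j|^p / N_R at a class member with similarity r_j (N_R = Σ over members
of |r_j|^p) and loses 1/(N − N_F) at a non-member; ES is the signed value
of *S* at its maximum absolute deviation. With p = 1 (default) members
are weighted by their similarity; p = 0 recovers the classical
equal-weight K-S form, for which *S* terminates exactly at zero — a
useful numerical self-check that the test suite exercises.

**Leading edge.** Members ranked at or before the ES peak constitute the
leading edge; their recorded best-match query residues are the
explanation of the call. We use the standard peak-prefix definition of
the leading edge; an alternative phrasing ("members scoring above the
maximum running sum") is not directly computable, and the peak-prefix
set is the established semantics for the statistic. Only positive ES can
produce a call: depletion of a class carries no annotation evidence.

## Significance

Raw ES values are incomparable across classes because class size and
within-class embedding correlation shape each null. Label permutation is
known to over-report significance for internally correlated sets — our
own synthetic experiments reproduce this: with few, tight classes, a
*null* query often ranks some class's entire membership on top, giving
|ES| ≈ 1. Significance is therefore assessed against a
**function-specific empirical null**: for each class, the ES of every
background protein not annotated with that class. The empirical P-value
is the right tail p = #{d_i ≥ s}/|D| (ties counted toward the tail,
conservative). Two alternative conventions are kept behind
`pvalue_mode`: `pseudocount`, (1 + #{d_i ≥ s})/(1 + |D|), which is never
exactly zero and exactly calibrated under exchangeability; and
`literal`, #{s > d_i}/|D|, an anti-monotone audit variant retained for
compatibility only — it must not be used for calling.

BH step-up is applied across the classes tested for one query protein
(the per-protein family of hypotheses; a per-dataset scope can be had by
pooling results before correction). A call requires q ≤ threshold
(default 0.001, inclusive) and ES > 0.

**Background size.** An empirical null of size n cannot produce p below
1/n, and each query tests every class, so spurious calls at FDR
threshold t occur at a design rate of roughly (number of classes)/(n+1)
per query. The background cohort should therefore satisfy
n ≫ classes/t. The shipped synthetic study (20 classes, t = 0.001) uses
n = 10,000 background proteins, putting the per-query spurious-call rate
near 0.2%. Backgrounds smaller than 50 proteins per class are accepted
but flagged low-power.

## Reference database and geometry

Reference sites are built from a catalytic-residue table: per class, the
reference chain is parsed (first model; highest-occupancy altloc
conformer), heteroatoms — waters, ligands, ions and modified residues —
are removed (a switch can instead rename MSE→MET and keep it), and the
catalytic set is expanded to every residue with *any* atom within 3.5 Å
of *any* catalytic atom (boundary inclusive). Distances use all atoms
present in the file, including hydrogens if any; the criterion is
deliberately unqualified. Residue identity is author numbering with
insertion codes. Database residue order is significant — it is the
deterministic tie-break of the ranking — and is preserved by
serialization.

For predicted structures the B-factor column carries pLDDT; the
per-residue value is taken from the residue's first atom (predicted
models write a constant per residue) and falls back to the atom mean
with a warning if atoms disagree. Residues below 70 (inclusive cutoff)
are excluded from embedding; experimental structures bypass the filter.

**Superposition filters.** Proteome-scale scans are post-filtered for
structural agreement of the catalytic machinery. A reference catalytic
residue counts as identified only when it lies in the leading edge *and*
its mapped query residue has the identical amino acid. The filter
requires coverage ≥ 0.75 (inclusive), ≥ 2 matched residues, and
all-atom RMSD < 5 Å (exclusive) after Kabsch superposition of the
matched residues, with atoms corresponded by name and unmatched atoms
skipped. The Kabsch solver is the closed-form SVD solution with the
reflection correction, so the rotation determinant is always +1;
rank-deficient (e.g. collinear) point sets return a result with a
degeneracy warning since the axial rotation component is then arbitrary.

## Ranking determinism

All tie-breaks are fixed: database residues with equal scores keep
ascending database order; when several query residues tie as a database
residue's best match, the lowest residue number (then input order) wins;
the ES peak takes the first position attaining the maximum |S|.
Consequently reruns are byte-identical, and the `--threads` option never
changes results (computation is vectorized in-process, not sharded).

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the method relies
on: class centroids uniform on the unit sphere, members =
centroid + isotropic Gaussian noise σ renormalized (σ controls
within-class cosine spread monotonically), planted sites as noisy copies
of a class's members carrying the reference amino acids, and background
residues as fresh isotropic unit vectors (near-orthogonal to everything
in high dimension). Default study conditions: 20 classes × 10 residues
(3 catalytic), d = 64, σ = 0.1 within the reference, planted-query noise
0.05 with 200 background residues. All generators take explicit seeds;
there is no global RNG state.

They deliberately do **not** emulate: realistic protein geometry, the
similarity structure of a trained embedder (e.g. correlated classes of
chemically related mechanisms), AlphaFold error modes such as
low-complexity or disordered regions, or homologous contamination
between query and reference. Passing synthetic tests therefore
demonstrates the correctness and calibration of the statistical
machinery under its own assumptions — not annotation accuracy on real
proteomes, which depends on the embedder and reference curation.

## Numerical choices and degenerate inputs

* Embeddings are stored as float64 and never re-normalized at ingest
  (cosine similarity is scale-invariant); zero-norm vectors are rejected.
* Similarities are clipped to [−1, 1] only against floating overshoot.
* A class whose members fill the entire ranked list, or whose member
  similarities are all exactly zero (undefined N_R), is an error.
* Empty queries (e.g. all residues below the confidence cutoff) yield a
  structured "unannotatable" result; classes without a background are
  reported untestable rather than silently skipped.
* Mann–Whitney U (the baseline statistic) uses exact enumeration up to a
  combined sample of 12 and the tie- and continuity-corrected normal
  approximation beyond; the background-swap baseline feeds −log10 p into
  the same empirical-null machinery so that larger always means more
  enriched.
* The five frequency bins for per-class evaluation default to
  [1,5), [5,20), [20,50), [50,100), [100,∞); only the rare (<5) and
  validation (≥100) boundaries are fixed by design, the middle edges are
  configurable.

## Known limitations

* Annotation quality on real structures is bounded by the plugged-in
  embedder and by reference-site curation; neither is shipped.
* The empirical null only covers proteins resembling the background
  cohort; queries far outside it (the synthetic analogue would be
  adversarially structured embeddings) can still produce spurious calls,
  which is what the structural post-filters are for.
* Multiple bound conformations, alternate locations beyond
  highest-occupancy selection, and flexible or sequence-order-independent
  site alignment are out of scope.
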
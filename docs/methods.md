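# Methods

`fibryze` implements the computational layer of an in-silico fibrinolysis
study: given the substrate specificity of a cysteine protease (actinidin,
the papain-family protease of kiwifruit, catalytic triad
Cys25–His162–Asn182), it predicts cleavage sites on fibrin chains, builds
the peptides that would be docked against the enzyme, screens docked
poses for catalytic competence, summarises trajectory observables, and
performs the statistics of the accompanying clot-lysis assay. Structure
prediction, docking searches and molecular-dynamics integration are
explicitly out of scope: predicted models, poses and trajectories are
*inputs* (PDB files), and this package is the analysis layer over them.

## Cleavage-site model

Substrate positions use Schechter–Berger notation: P4…P1 run N-terminal
of the scissile bond, P1'…P4' C-terminal; the P1–P1' peptide bond is the
one cleaved. A `SpecificityModel` is a set of *evidence sources*, each a
mapping from position tag to an allowed-residue set; absent tags are
unconstrained. The bundled actinidin model (`data/actinidin.yaml`)
carries two sources: kiwellin-derived evidence constraining only
P1 ∈ {T,H,R} and P1' ∈ {T,S,G}, and insulin-degradation evidence
constraining all eight positions.

Combination is `any_source` by default: a position is a site when at
least one source is fully satisfied. This is the only simple rule
consistent with the four canonical fibrin sites (Aα Arg162–Gly163
matches the kiwellin source; Aα Arg171–Glu172 and γ Lys406–Gln407
require the insulin source; Bβ Arg346–Gly347 matches both);
`all_sources` is available in the config for stricter enzymes. The
kiwellin column is interpreted as independent per-position sets
({T,H,R} × {T,S,G}), not as three literal pairs, because the definition
is presented as columns of allowed residues per position; a config can
express the literal-pair reading as three single-residue sources if
desired.

Scanning rules: a source only matches when *every* constrained tag maps
onto the sequence — windows truncated by a terminus fail (conservative;
no wraparound), and windows never span an author-numbering break
recorded during sequence extraction from a structure. Windows containing
`X` at a constrained position are reported as indeterminate, never as
matches. All positions are reported in author numbering, 1-based.

## Docking windows

Each site yields one peptide: up to `flank` residues (default 10) on
each side of the scissile bond, i.e. a 20-mer centred on the bond for
interior sites, truncated at termini and numbering breaks. Sites closer
together than `flank` are *not* merged — one scissile bond is docked per
complex, so each site gets its own window.

## Structural metrics

All first-principles, with independent oracles in the test suite:

* **Superposition** — Kabsch's SVD solution with the reflection
  excluded (det(R) = +1 always); RMSD is reported after applying the
  optimal transform. Rank-deficient (collinear) point sets raise an
  error because the optimal rotation is not unique. The test oracle is
  Horn's quaternion method, implemented separately.
* **Trajectory RMSD** — each frame is least-squares fitted to the
  reference frame *on the same selection it is scored on* (the MD
  convention), no mass weighting; the default selection is backbone
  N/CA/C.
* **Torsions** — φ(i) = dihedral(C(i−1), N(i), CA(i), C(i)),
  ψ(i) = dihedral(N(i), CA(i), C(i), N(i+1)); sign convention cis = 0°,
  positive clockwise viewed from the first atom towards the last
  (stated explicitly; the four-point worked example
  (1,0,0),(0,0,0),(0,1,0),(0,1,1) gives −90°). Ramachandran regions are
  *data*, not code: coarse rectangular polygons for the favored
  (β/extended, right-handed α, left-handed α) and allowed regions,
  swappable via the `regions` argument. They approximate the usual
  general-case contours; no claim is made of matching any published
  contour set, and no published-contour number is asserted anywhere.
* **SASA** — Shrake–Rupley with a Fibonacci (golden-spiral) point
  lattice, default 960 points and 1.4 Å probe; a point is exposed iff
  outside every neighbour's expanded sphere (KD-tree neighbour search).
  Bundled van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20 Å — common SASA practice, overridable per call and echoed in
  the result metadata. At 960 points the isolated-atom closed form is
  met to ≲0.5% and the two-sphere cap formula to ≲2%; 960 vs 4000
  points differ by <1% on fixtures.
* **Distances** — plain Euclidean distances between uniquely resolved
  atoms; ambiguous selections are an error listing the matches.

## Pose screening and trajectories

A docked pose is catalytically competent when the distance from the
nucleophile key atom (Cys SG) to the scissile carbonyl carbon (the
"SG–C distance") is within a threshold: default 5.0 Å, with 4.5 Å the
common stricter alternative; the verdict is `accept` iff
sg_c ≤ threshold, and the threshold used is always echoed. The His and
Asn triad atoms are located and their distances recorded but not gated —
their orientation was screened visually in the source workflow, which
does not reduce to a stated numeric criterion.

Hydrogen bonds are geometric: donor–acceptor (N/O/S) distance
≤ 3.5 Å and, when the donor carries a covalent hydrogen, H–D–A angle
≤ 30° (the usual MD-engine convention, since no criterion is stated by
the assay this mirrors). Without hydrogens the distance criterion
applies alone, logged. Intra-selection pairs are excluded and each
(D,A) pair counts once.

Trajectory summaries report per-frame values, mean ± SE, and the
five-number summary (min, Q1, median, Q3, max) with linear-interpolation
quartiles (`numpy.percentile`, `method="linear"`), matching
whisker-box-plot usage.

ΔG and Kd are related by ΔG = RT ln Kd with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 310.15 K; Kd is the
dimensionless exponential with no standard-state conversion. The two
conversions are exact mutual inverses.

## Clot-lysis statistics

The degradation percentage follows the assay formula
(initial − final)/**final** × 100 computed on dry weights. Division by
the *final* weight is unusual (most assays divide by initial); it is
kept as the default because it is the assay's printed definition, and
`fraction_of_initial` is an explicit alternative, echoed in every output
row.

Group comparison is classical one-way ANOVA from sums of squares
(df_between = k−1, df_within = N−k), followed by pairwise t tests
(pooled variance by default, Welch by flag) adjusted by **both**
Bonferroni and Holm step-down, reported side by side — the assay
protocol names both and does not say which decided significance. The
degenerate all-identical case takes the F = 0, p = 1 path; a
zero-variance pair resolves by comparing means. Note a worked example
for calibration: raw pairwise p {0.010, 0.030, 0.040} at α = 0.05 gives
exactly one rejection under Bonferroni (0.03 ≤ α) *and* exactly one
under Holm, since the step-down stops at 0.030 > 0.05/2 (adjusted p
0.03, 0.06, 0.06). Group letters (compact letter display) are derived
from the Holm decisions over groups ordered by mean.

## Synthetic data: what it emulates and what it does not

Every analysis has a generator that plants its ground truth:

* `gen_sequence` — background drawn from residues that can never occupy
  P1 *or* P1' under the model ({C,I,M,P,W} for actinidin), with 8-mer
  motifs planted from one source's sets; the draw is rejection-sampled
  until a scan confirms exactly the planted sites, so the "exactly k
  sites" guarantee is checked, not assumed. (Excluding only P1'
  residues, as a weaker reading would have it, does not prevent
  spurious kiwellin matches at plant boundaries.)
* `gen_polypeptide` — backbone built by internal-coordinate (NeRF)
  placement with ideal geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å;
  angles 111.2°, 116.2°, 121.7°), so measured torsions equal the
  requested (φ, ψ, ω) exactly.
* `gen_pose` / `gen_trajectory` — a minimal enzyme (Cys25 with SG at
  the origin, His162/Asn182 key atoms, six CA anchors) and a peptide
  whose scissile carbonyl sits at exactly the planted SG–C distance;
  trajectories add per-frame planted distances, ideal hydrogen-bond
  pairs (D–A 2.9 Å, H–D–A 10°) bridging the chains, Gaussian jitter on
  anchors and peptide backbone, and an optional non-rigid peptide
  drift. Profile helpers produce Gaussian series with planted quartiles
  and early-relaxation-then-plateau shapes. The planted distance and
  hydrogen-bond atoms are never perturbed, so recovery is exact and
  hydrogen-bond counts are constant per run — deliberately so; the
  statistics layer handles the resulting zero-variance groups.
* `gen_clot_table` — degradation percentages drawn N(mean, σ) and
  back-solved into final dry weights under the chosen convention.
  Defaults are the study conditions of the assay this mirrors: control
  12%, mid dose 55%, high dose 73% mean degradation, replicate SD 2.0
  (≈ the reported standard errors × √3), n = 3, initial clot weight
  0.12 g (clots of 0.10–0.15 g).

These fixtures are geometric scaffolds, not physical structures: no
force field, no solvent, no docking decoys, bond graphs not realistic
away from the measured atoms. Passing tests therefore demonstrate that
the *analysis* is correct (each measurement inverts its generator and
matches independent oracles and closed forms), not that any particular
real enzyme–substrate pair behaves this way. Real structures, poses and
trajectories enter as user-supplied PDB files. Likewise the
sequence-level results run on synthetic stand-ins — a 218-residue pair
differing only at position 101 (E vs D), and fibrin-like chains with
motifs planted at the canonical author positions (Aα 162/171, Bβ 346,
γ 406) — labelled synthetic throughout; the real reference sequences
are user-supplied FASTA.

## Numerical choices and problem sizes

* Sequence scanning, window building and identity are exact
  (alignment tie-breaks resolved by taking the aligner's first optimal
  alignment, a deterministic leftmost-gap choice; identity denominator
  is the aligned length including gaps, reported to one decimal).
* Five-number quartiles: linear interpolation. RMSD fitting excludes
  reflections. Degenerate inputs raise typed errors rather than
  returning silent values (collinear clouds, ambiguous atom selections,
  zero clot weights, Kd ≤ 0).
* The analysis drivers use 2,000-frame trajectories for the per-complex
  summaries; quartile-recovery and negative-control contrasts in the
  acceptance script use 10,000 frames. The ANOVA type-I calibration
  uses 1,000 null replicates of three n = 3 groups, chosen to give a
  standard error of ≈0.7 percentage points on the 5% rate.
* All randomness flows through `numpy.random.default_rng` seeded per
  generator call; identical seeds give bit-identical fixtures.

## Known limitations

* The Ramachandran polygons are coarse; classification near region
  edges is approximate and intended for sanity checks, not validation
  scores.
* Hydrogen-bond detection with missing hydrogens reduces to a distance
  cut, which overcounts relative to angle-aware criteria.
* `map_chains` uses greedy bijective assignment by identity; for
  structures with more chains than references it falls back to reusing
  references, which is correct for duplicated crystallographic chains
  but not for genuinely novel chains (those are left to the 30%
  identity floor and a warning).
* The pipeline treats poses and trajectories as given; it does not
  attempt to judge force-field quality, convergence, or binding-energy
  rescoring.
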
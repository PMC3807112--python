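# Methods

## Flux-space geometry

The steady-state assumption *S·v = 0* makes the kernel of the stoichiometric
matrix the set of all admissible flux distributions. Boundary species
(compartment tag `b`, or the SBML `boundaryCondition` flag) are exempt from
mass balance and excluded from the rows of *S*, so exchange fluxes are free;
without this the kernel of a closed network would often be trivial.

Before the decomposition the columns of *S* are normalized to unit
Euclidean norm. Multiplying a reaction's stoichiometry by a scalar only
changes the unit in which its flux is measured, so no angle should move;
with raw columns it does (the kernel transforms by the inverse scaling),
while normalization makes scale invariance exact. Column scaling cannot
change which kernel rows are collinear, so the set of fully coupled pairs,
the blocked set, and every zero angle are identical under either convention;
only the magnitudes of non-zero angles differ. Raw-unit flux directions are
recoverable by dividing the rows of the stored basis by the recorded column
norms.

The orthonormal basis comes from `scipy.linalg.null_space` (SVD,
rank-revealing). The projection of reaction *i* is `p_i = K·K[i]`, with norm
`‖K[i]‖`. Angles are folded to [0°, 90°] with an absolute cosine so that a
reaction and a direction-reversed but fully coupled partner score 0°; the
sign with which a reversible reaction is written is arbitrary, and without
folding it would flip 0° to 180°. Reversible reactions are kept as single
signed columns — splitting them into forward/backward halves would give
every reversible reaction a perfectly anti-parallel twin and confound the
zero-angle identity.

A note on duplicated reactions: a second copy of a reaction creates an
alternative parallel route, so the flux ratio between original and copy is
*not* fixed and their angle is positive (≈48° for a copy of the middle step
of a 3-step chain). This is the correct behaviour — the LP flux-coupling
audit agrees — even though one might intuitively expect identical columns to
look identical; they are identical only as columns, not as flux coordinates.

Numerical policy: a reaction is blocked when its projection norm is ≤ 1e-8;
two reactions are fully coupled when their angle is ≤ 1e-4°; matrix ranks
zero out singular values ≤ 1e-9·σ_max. These sit a few orders above
double-precision orthogonalization error at genome scale and are exposed as
configuration. Angle comparisons in tests tolerate 1e-5°, because arccos
near cos = 1 amplifies an ε-level cosine error to √(2ε) radians. The angle
matrix is computed in row blocks, and the decomposition can be cached on
disk keyed by a content hash of *S*, since it dominates runtime for
genome-scale models.

## From expression to h-values

Growth rate is μ = ln 2 / t_d (doubling time in hours). Spearman correlation
uses midranks for ties and the t approximation on n−2 degrees of freedom for
two-sided p-values (identical to scipy's default); zero-variance genes are
flagged undefined and excluded from selection. The two-group mode uses
Welch's unequal-variance t-test with the convention that positive statistics
mean higher expression in the case (deceased) group.

FDR control is Benjamini–Hochberg. A direction-restricted selection
("positively correlated genes") restricts the family to genes with the
concordant sign and halves their two-sided p-values — positive and negative
sets are selected separately. Probe-level tables collapse to genes by
minimum p, the rule that preserves any significant probe. These are the
standard choices for microarray-era designs; an empirical-null alternative
was considered and not implemented, BH being the default any practitioner
would reach for.

The per-reaction score is h = 1 − min one-sided p over the reaction's GPR
leaf genes. Min-p is an OR-like aggregation: one strongly associated isozyme
suffices, which matches treating single-gene evidence as sufficient for a
reaction. Fisher's combination is available behind the `aggregation`
argument. Complexes (AND) and isozymes (OR) are not distinguished when
mapping gene sets onto reactions — any leaf match counts. Reactions without
gene association keep h = 0 and can enter sub-networks only through the
coupling expansion.

## Sub-network detection

Seeding takes the non-blocked reactions with h ≥ h_min (default 0.95 in
correlation mode; 0.80 in the two-group mode, where significance is
systematically weaker and the procedure is deliberately not built on a
stringent cut-off), connects pairs with θ ≤ θ_max (default 15°), and keeps
connected components with ≥ 2 members. Single-linkage components were chosen
over parametric clustering because they reproduce the two-phase
"cluster, then close under coupling" design with no extra free parameters;
the thresholds are calibration choices exposed in configuration. Expansion
unions the full-coupling classes of all seed members; the result is
connected in the reaction–metabolite sense because each class shares a
one-dimensional flux mode. Ranking is by reaction count, ties by mean seed
h, then lexicographic first reaction id; overlapping sub-networks are
reported as-is.

## Robustness and essential metabolites

Only metabolites *unique* to a sub-network (touched by no outside reaction;
boundary species excluded) contribute balance rows:
DOF = |reactions| − rank(S restricted to unique metabolites × members).
This is the only convention under which both canonical cases hold — a series
pathway has DOF 1 and n parallel routes have DOF n. Uniqueness is assessed
per compartment-qualified metabolite id; pooling across compartments would
merge distinct species and is not done.

Blocking a metabolite removes every member reaction touching it (equivalent
to adding v = 0 constraints, simpler to audit); the metabolite is essential
when the surviving reactions' DOF is 0, with the convention that an emptied
reaction set has DOF 0. All rank computations share the 1e-9 relative
singular-value tolerance.

## Overlap statistic

The universe is all non-boundary model metabolites; the two sets are the
metabolites unique to each sub-network collection (uniqueness relative to
the whole model). The null is hypergeometric with fixed set sizes, and
p = P[X ≥ observed] is accumulated by log-sum-exp over exact log-pmf terms,
so tails around 1e-50 keep a meaningful log value. A per-metabolite
Bernoulli null would be an alternative; the fixed-size null matches how the
sets are actually constructed.

## Energetics fixture

The packaged `fa_cycle` model encodes one elongation/β-oxidation round
amortized per cycled acetyl-CoA: acetyl-CoA carboxylase (1 ATP), one FAS
condensation (2 NADPH), the carnitine shuttle, one β-oxidation round
(1 FADH2 + 1 NADH, mitochondrial), citrate synthase, the citrate–malate
antiporter, ATP-citrate lyase (1 ATP), and the paired malate dehydrogenases
(−1 NADH cytosolic, +1 NADH mitochondrial). Two deliberate simplifications:
a synthetic carrier-return step brings the shortened acyl chain back to the
cytosol so the per-round cycle closes (physiologically the chain is built
fully and degraded fully; per-C2 accounting is the large-chain limit), and
the 2-ATP acyl-CoA activation is excluded as amortized over chain length.
Cofactors are boundary species — the carbon skeleton alone defines the
one-dimensional flux space — and carry their compartment in the id suffix
(`atp_c`, `nadh_m`) because boundary species have no model compartment of
their own.

Respiratory yield credits the mitochondrial gain (2 NADH + 1 FADH2 per
cycle) at the NADH P/O ratio, FADH2 at 2/3 of it — the only linear
convention consistent with a yield of 8 ATP at P/O 3 and 4 ATP at P/O 1.5.
The cytosolic NADH debit is one of the three oxidized cytosolic cofactors
and is not subtracted from the respirable pool. Net cycle ATP subtracts the
2 ATP driving cost.

## Synthetic data: what it does and does not emulate

Toy models compose series chains (each one a full-coupling class, verified
at generation by an LP flux-coupling audit that is independent of the
kernel geometry), diamonds (uncoupled parallel branches) and disconnected
copies. Growth rates are log-uniform over 0.01–0.04 h⁻¹ — a 4-fold spread,
the range observed across a large cell-line panel; since the correlation
statistic is rank-based, the marginal shape is immaterial and log-uniform
merely spreads the ranks. The default design is 60 samples (the cell-line
panel size), planted-gene effect 1.0 on the rank-z scale against noise
sd 0.5 (Spearman ρ ≈ 0.9, comfortably detectable at n = 60 without making
detection trivial at n = 20), and 150 decoy genes.

Passing the planted-recovery benchmark shows the pipeline is correct, not
that it is powerful on real data: the generator has no probe effects, batch
structure, correlated backgrounds, partially coupled pathways, or
genome-scale topology, and real expression–phenotype effects are weaker and
non-monotone. Problem sizes throughout the test-suite simulations (200
genes × 60 samples × 100 replicates for the null-calibration check; ~20
reaction networks) were chosen as the smallest at which the statistical
properties under test are meaningfully exercised.

## Known limitations

- Partial and directional coupling are out of scope; only the angle
  continuum and full-coupling classes are computed.
- The h-value and the clustering thresholds are calibration choices; the
  defaults are documented above and surfaced in configuration rather than
  claimed optimal.
- `map_genes_to_reactions` ignores AND/OR semantics (any leaf match); a
  complex missing one subunit still counts as matched.
- The energetics auditor is generic over tabular cycle models, but only the
  packaged fixture is curated.
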
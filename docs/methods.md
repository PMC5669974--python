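# Methods

`rppacra` personalizes a signaling-network model to two tumour samples
from a reverse-phase protein array (RPPA) panel and asks which kinetic
parameters — and hence which pathway interactions — make the two
signaling states different and how robust each state is.  This note
records the model, the statistics, the defaults, and the design choices
made where the problem was genuinely open.

## Input data and divergence ranking

The unit of data is an antibody *endpoint*: one phosphosite (or total
protein) intensity per sample, in arbitrary units.  The shipped panel
compares a long-overall-survival (l-OS) and a short-overall-survival
(s-OS) lung-adenocarcinoma patient over 51 endpoints; the statistic is
always the ratio r = s-OS / l-OS.

* Ratios are recomputed from raw intensities; a printed ratio column, if
  present, is only cross-checked (2 decimals) and mismatches logged.
* A zero denominator with positive numerator is flagged `undefined-high`:
  divergent upward but with no finite value.  Zero over positive is a
  finite 0.  These endpoints are ranked most extreme on their side but
  cannot contribute a log-scale value to any aggregate.
* Divergence calling uses a symmetric fold rule, default 2 (r ≥ 2 or
  r ≤ 0.5).  On the shipped panel this flags 20 endpoints (4 up, 16
  down).  The rule is monotone in the threshold by construction.
* Phosphosites of one protein are combined by the geometric mean of
  their finite positive ratios (a log-scale average, matching the
  multiplicative error structure of the assay).  Total-protein
  antibodies are excluded from activation aggregates when the protein
  also has phospho endpoints; when a total antibody is the protein's
  only read-out it is kept as an activity proxy.
* Calibration proteins are chosen by ranking *model-mapped endpoints* on
  the signed divergence score (log2 r, with `undefined-high`/zero as
  side extremes) and greedily taking the k = 2 most extreme distinct
  nodes per side.  On the shipped panel this yields BAD and c-KIT
  (higher in s-OS) and RAF (via b-RAF S445) and p70S6K (lower in s-OS).
  Ranking endpoints rather than node aggregates is deliberate: a single
  strongly divergent phosphosite is a better calibration target than a
  node average diluted by unrelated sites.

## The pathway model

The network has 21 protein nodes spanning the EGFR/IGF1R–MAPK and
PI3K/AKT/mTOR cascades with the LKB1–AMPK energy-stress arm and the
BAD–caspase apoptotic output.  Each node carries a conserved total
(normalized to 1) split into active and inactive fractions; only the
active fraction a is integrated and the inactive fraction is 1 − a by
construction, so the conservation law is structural and exact.

Functional forms (active fraction a of the target, source activity
a_S):

* enzymatic activation:  k · a_S · (1 − a) / (K + 1 − a)
* enzymatic inhibition:  k · a_S · a / (K + a)
* mass action: the same without the saturating denominator
* basal deactivation:    − d · a  (every dynamic node)
* receptor stimulus: constant ligand drive through the saturating
  activation form, strength s and half-saturation Ks per receptor.

Both saturating forms vanish at the relevant boundary, so every state
stays in [0, 1] for any positive parameter vector; this is asserted
numerically after each solve rather than enforced by clipping.

The parameter ledger totals 86:

| group | count |
|---|---|
| 29 Michaelis–Menten edges (k, K) | 58 |
| 1 mass-action edge BAD→CASP (k) | 1 |
| 18 basal decays (dynamic nodes) | 18 |
| 4 receptor drives (s, Ks) | 8 |
| LKB1 basal activation | 1 |

Design choices behind that ledger:

* **Constant phosphatases.** RasGAP, RafPP and PP2A are constitutively
  active (activity 1, no dynamics of their own) — the standard treatment
  of phosphatase tone in signaling ODE models; their inhibitory edges
  carry sampled (k, K) like any other edge.
* **BAD→CASP is mass action.** BAD's pro-apoptotic action is
  stoichiometric sequestration, not enzymatic turnover, so it is the one
  non-saturating interaction.
* **BAD starts fully active.** BAD has no activating edge (survival
  signaling through AKT and p90RSK *inactivates* it), so its unstimulated
  state is active; all other dynamic nodes start at 0 except a 10⁻³
  receptor seed.  The evaluation functional is then the area under a
  transient response.
* **LKB1** is an input-like kinase: a basal mass-action activation
  balanced against ERK-mediated inhibition (the MAPK–LKB1 crosstalk).

Integration uses LSODA (stiff-capable) with rtol 10⁻⁶ / atol 10⁻⁹ and an
analytic Jacobian, over a default horizon T = 100 time units, on which
nominal trajectories are within ~10⁻⁷ of steady state.  Failures are
flagged per draw, never silently replaced; a failure rate above 5%
aborts the run.  The evaluation function of a node is the trapezoidal
AUC of its active fraction over [0, T].

## Conditional robustness and the MIRI

Parameters are perturbed jointly over a log-uniform box of ×10⁻²…×10²
around nominal (the standard ignorance range for rate constants),
stratified by Latin-hypercube sampling per free dimension.  Conditioning
the draws on a tail of an evaluation-function distribution induces, per
parameter, a conditional density; the moment-independent robustness
indicator (MIRI) of a parameter is the total-variation distance between
its two tail-conditioned densities:

    MIRI = ½ ∫ |f_L(θ) − f_U(θ)| dθ  ∈ [0, 1]

estimated by Gaussian KDE with a common Silverman bandwidth on a shared
512-point grid.  A 64-bin histogram L1 estimator ships as an independent
cross-check (they agree within 0.05 at n ≥ 5000).  Inside the sampling
pipeline densities are estimated on log₁₀ θ: total variation is
invariant under smooth monotone reparameterization, and the conditional
densities are far better behaved on the sampling scale.

Two practical choices:

* **Tail fraction** α = 0.10 by default, configurable.
* **Noise floor.** The KDE total-variation between two finite samples of
  the *same* density is biased upward (≈ 0.05 at tail size 500).
  Pipeline-level MIRIs therefore subtract a permutation-null floor (the
  mean statistic over three seeded re-splits of the pooled conditioned
  samples) and clamp at zero, so structurally irrelevant parameters
  score at statistical zero.  `compute_miri` without correction remains
  the raw, declared estimator.

## Calibration

The four calibration proteins with their signs define joint directional
tails: the "s-OS-like" draw set intersects the upper α-tails of the
'+' proteins with the lower α-tails of the '−' proteins; "l-OS-like" is
the opposite corner.  Independent tails shrink like αᵐ, so with four
proteins the literal intersection is usually below the 20-draw minimum
needed for density estimation; the conditioning then falls back (logged)
to ranking draws by the mean direction-signed standardized evaluation
value and taking the extreme α-fractions.

Per realization (default 3 × 5000 draws; reference scale 10 × 100000):
sample, simulate, condition, score every parameter.  Parameters whose
mean MIRI exceeds the upper boxplot fence (Q3 + 1.5 IQR — the natural
reading of a box-plot-with-cutoff presentation; the alternative is an
explicit cutoff) are fixed: the s-OS model pins each to the *median* of
its s-OS-like conditioned draws pooled over realizations, the l-OS model
to the opposite tail's median.  The median is robust and guaranteed to
lie inside the induced tail; swapping patient labels swaps the fixed
values exactly.  Both patient models share the remaining free space.

## Validation

Both patient models are sampled over the shared free space with **common
random numbers** (the same hypercube draws), so the patient comparison
is paired and identical models tie exactly.  Per patient: per-node AUC
densities over realizations (default 5 × 2000; reference 100 × 10000),
a node × free-parameter MIRI matrix from each node's own distribution
tails, and the grand mean of that matrix as the patient's *overall
robustness* (one of several defensible aggregations; the mean is ours).
Directionality ("higher"/"lower" in s-OS) is read from mean AUCs — the
mean rather than the density mode for estimator stability — and matched
against the RPPA ratio direction where an endpoint exists; nodes without
RPPA coverage (e.g. KRAS) are reported prediction-only.

The s-OS − l-OS MIRI difference matrix is row-clustered (Euclidean,
average linkage) and exported with its dendrogram in Newick text.

Validation read-outs are chosen graph-theoretically: closeness
centrality CC = (n−1)/Σd and eccentricity E = max d on the undirected
interaction skeleton (within connected components), ranked
lexicographically CC-first with alphabetical tie-breaks, restricted to
RPPA-measured non-calibration nodes.  On the default network the top
ranks include ERK and mTOR; the report always additionally covers the
canonical ERK/AMPK/mTOR trio.

## Synthetic data

The generator emulates the panel's structure: l-OS baselines uniform on
10³–7×10⁴ a.u., s-OS = baseline × planted fold × exp(N(0, σ)) with
σ = 0.2 by default (multiplicative, as RPPA variation is), optional
multi-phosphosite proteins, fully seeded.  It does *not* emulate spatial
array artifacts, antibody cross-reactivity, or inter-protein intensity
correlation — so passing recovery tests demonstrates the selection
logic's operating characteristics under idealized noise, not performance
on raw arrays.  At fold 4, σ = 0.2 and threshold 2, per-endpoint
miss/false-call probabilities are Φ(−3.47) ≈ 3·10⁻⁴, hence the ≥ 99%
recovery / ≤ 1% false-positive check.

## Scales, determinism, limitations

* Scale presets: `paper` (calibration 100000×10, validation 10000×100),
  `desk` (5000×3, 2000×5, minutes on one CPU — the default and the scale
  used by the test suite and `scripts/acceptance.py`), `tiny` (smoke).
* All stages derive per-realization seeds from one root seed via
  `SeedSequence`; reruns are bit-identical and the calibration stage is
  cached against a config hash.
* The kinetic forms and the default edge list are a reconstruction of
  these cascades from standard pathway resources (KEGG) and the lung
  cancer signaling literature; analyses that
  depend only on directionality, ordering and robustness *differences*
  are meaningful under such a reconstruction, while absolute MIRI
  magnitudes are estimator- and parameterization-specific and should not
  be compared across models.  Two-sample designs have no biological
  replication; the stability checks across realizations and seeds bound
  Monte-Carlo, not biological, variability.
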
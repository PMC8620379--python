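# Methods

## The model

`raftsim` simulates lateral lipid organisation in a cell-membrane
monolayer as a stochastic cellular automaton on a periodic 200 × 200
lattice. Each site holds one of seven coarse-grained lipid classes
(cholesterol, sterol esters, DHA, n-6 LCPUFA, monoenes, saturates,
sphingolipids). A lipid class is represented geometrically as a cylinder
of radius *R* and length *L* (Å, calibrated on mouse frontal-cortex
membranes), and two neighbouring lipids attract through the non-retarded,
additive London–Van der Waals energy of parallel cylinders at surface
separation *D*:

    LVW_ij = A·L / (12·√2·D^{3/2}) · √(R_i·R_j / (R_i + R_j))

with *A* the Hamaker constant. Water is not modelled. For a heterogeneous
pair the single *L* is the arithmetic mean of the two class lengths, which
keeps the 7 × 7 interaction matrix symmetric and reduces to the plain
formula within a class.

### Dynamics

Each iteration visits every site once in a fresh random permutation; the
visited site proposes to exchange with one uniformly chosen von Neumann
neighbour. The default acceptance rule is an inverse-force law,

    p(move) = exp(−(B_cur − B_ref) / θ),

where `B_cur` is the summed neighbour binding of the two participating
sites (8 bonds, the shared bond counted twice, consistently) and
`B_ref = 8·min(LVW)` anchors the weakest possible neighbourhood at
p ≈ 1. Strongly bound neighbourhoods therefore move rarely, and because
immobile strong binders accrete further strong binders, low-mobility
domains nucleate and grow — the mechanism that produces lipid rafts here.

A Metropolis rule on the binding change of the exchange,
`p = min(1, exp((B_swap − B_cur)/θ))`, is available behind
`swap_rule="metropolis"` for sensitivity checks. It is **not** the default
for a structural reason worth recording: with the mean-length convention
the pair-energy matrix is nearly additive (the cross-pair energy is within
~0.1% of the mean of the two self-pair energies), so the energy change of
any exchange is almost zero and Metropolis dynamics is indistinguishable
from free diffusion — no domains ever form. The inverse-force law depends
on the absolute local binding rather than its exchange difference and is
also the literal reading of how swap reluctance is usually described for
this class of model.

Mobility of a site is the fraction of iterations in which it changed
position (either as proposer or as the selected partner). Identical-class
exchanges are subjected to the same acceptance law and count as movement
by default (`count_identical`), so mobility reflects binding strength, not
class boundaries.

### Parameters

| parameter | default | meaning / why |
|---|---|---|
| lattice | 200 × 200, periodic | ~40,000 lipids; periodic boundary avoids edge artifacts in domain statistics |
| iterations | 1000 | reaches a steady distribution of low-mobility regions at this scale |
| replicates | 10 | scenario outputs are reported as mean ± SD over 10 seeded repeats |
| A (Hamaker) | 1 × 10⁻¹⁹ J | vacuum magnitude for lipids (10⁻²⁰–10⁻¹⁹ J); only the ratio to θ matters |
| D | 1.50 Å | intermolecular surface distance from the calibrated geometry table |
| θ | 4 × SD of the 28 pair energies | half the natural spread of the 8-bond binding sum; smaller θ freezes the whole lattice, larger θ gives free diffusion |
| raft threshold τ (scenarios) | 15th percentile of pooled Control mobility | one fixed τ across conditions (the original calibration fitted a single constant); the stage patterns are insensitive to the exact percentile within ~12–22 |
| raft threshold (single map) | lower mode of a bimodal mobility histogram, else 10th percentile | data-driven fallback when no reference condition exists |

### Raft statistics

Rafts are the connected regions with mobility strictly below τ. The size
estimator is a row-by-row scan collecting maximal horizontal runs of raft
cells (periodic wrap merged): its mean is a mean chord length. The count
estimator assumes circular domains: `count = raft_area / (π (d/2)²)` with
the effective diameter `d = (4/π) · mean_chord` (the mean chord of a disc
of diameter *d* over uniformly spaced rows is (π/4)·d). The correction is
on by default and makes the indirect estimator agree, within ±1, with
direct connected-component labelling (4-connectivity with periodic seams
merged) on synthetic disc masks — the package's geometric oracle.

### Peroxidability

The peroxidability index of a composition is the linear score
`PI = 0.025·%monoenes + 5·%n-6 LCPUFA + 6·%DHA` (bounded by 600 for pure
DHA). PI maps tile the lattice into non-overlapping 5 × 5 patches, convert
each patch's 25 cells to percentages and score them. Domain PI applies the
same score to the inside-raft, outside-raft and whole-lattice
compositions; by linearity the whole equals the area-weighted combination
of the parts, which the tests assert exactly.

### Validation

The validation statistic is the quadratic difference
`Δ² = Σ_classes (p_a − p_b)²` (squared percentage points). An ensemble of
membranes with random compositions — symmetric Dirichlet(α=1) on the
7-class simplex — is pushed through the same simulate→segment pipeline,
and empirical 2.5/97.5 percentile intervals are formed for (i) Δ² between
a membrane and the raft simulated from it, and (ii) Δ² between a simulated
raft and the experimental raft composition. For all four neuropathological
conditions the data-driven quantity (ii) falls *below* the random
interval: simulated rafts are far closer to measured rafts than chance.
Quantity (i) for the real compositions falls *inside* the random interval
in this implementation (random Dirichlet membranes span an enormous Δ²
range), so the package reports both verdicts and does not claim the
panel-(i) exclusion.

## What the generator emulates — and what a green test establishes

The simulated membrane is a single leaflet with no proteins, no explicit
solvent, no flip-flop and no physical length calibration of the lattice
pitch; raft sizes are in lattice-cell units and are not comparable to nm.
The stochastic acceptance tests (enrichment, stage trends, Δ² validation)
establish that the *mechanism* — composition-driven differential mobility —
reproduces the qualitative neuropathological patterns (fewer and larger
rafts plus lower non-raft peroxidability in late-stage membranes), not
that the absolute domain dimensions are physiological.

## Numerical choices

- All randomness flows from a single `numpy.random.Generator` per run;
  (composition, config, seed) determine the trajectory bit-exactly.
- Site counts are allocated by largest-remainder rounding (ties broken by
  class code), after normalising the row sum, so printed tables that sum
  to 100.01 still allocate exactly H·W sites.
- The RMSD noise series is computed on the per-site binding-energy field
  relative to iteration 0 (one of several possible readings; logged in the
  result object so alternatives can be swapped in).
- Empty or full raft masks raise an explicit `EmptyRegionError` (or yield
  NaN for the affected PI) rather than returning silent zeros; random-
  ensemble draws with degenerate masks are resampled and the resample
  count bounded.
- Force-field matrices are clamped to exact symmetry
  (`min(E, E.T)`) against float noise in assembly.

## Known limitations

- The acceptance rule and θ are a reconstruction: the original calibration
  is unpublished. Both are exposed in `SimulationConfig`.
- The count estimator's circular-domain assumption degrades near
  percolation (late-stage membranes at high τ).
- The "cumulative PI" of a scenario is reported as the patch mean; a
  patch-sum alternative is a one-liner on the exported map.
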
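# Methods

This note records the model, the numerical choices and the limits of what the
test suite demonstrates. It is the reference for every constant that is not
forced by the method itself.

## Pose model and discretization

A pose is `x = (t, e, φ) ∈ R^(6+k)`: centroid translation `t` relative to the
binding-sphere center (Å, bounded by the sphere's axis-aligned box
`[−r, r]³`), Z–Y–Z Euler angles `e` (degrees), and torsions `φ` (degrees) of
the rotatable bonds in detection order. A bond is rotatable iff it is single,
acyclic, between heavy atoms, and both ends carry a further heavy neighbor;
amide C–N bonds are excluded by default (planarity) and can be re-enabled.
Each torsion rotates the branch with fewer heavy atoms (ties: the branch with
the higher-indexed atom). Euler angles rather than quaternions keep every
orientation coordinate a `[0, 360]` rotational dof with its own pheromone
table.

Every dof interval `[a_i, b_i]` is partitioned into `n_i` closed
sub-intervals. The characteristic (indicator) assignment maps a value to the
interval containing it; shared endpoints — where the closed intervals
overlap — go to the lower-indexed interval, and `a_i` to interval 1. Default
steps are 1° for angles and 0.5 Å for translations; coarser grids are used
wherever an exhaustive oracle must enumerate the cells.

## Scoring functions

All three scoring functions are sums of four terms (units are dimensionless
score units; more negative = better):

* **Steric**: per receptor-heavy/ligand-heavy pair, piece-wise linear in the
  distance `r`: `w_clash (A − r)` below `A`; linear from 0 at `A` to the well
  depth at `B`; flat on `[B, C]`; back to 0 at `D`; 0 beyond. Pairs where
  both atoms are N or O use a shorter, deeper "polar" breakpoint set.
* **Hydrogen bond** (chemplp only): for each donor–H···acceptor triple,
  `w_hb · block(|d − d₀| / σ_d) · block(|θ − 180°| / σ_θ)` with
  `block(u) = max(0, 1 − u)`. Donors are H atoms bonded to N/O; acceptors
  are N/O.
* **Internal clash**: the repulsive branch only, over ligand heavy-atom pairs
  at graph distance ≥ 4 bonds (standard 1–4 exclusion).
* **Torsion**: `k (1 + cos(nφ − φ₀))` per rotatable bond, keyed by the
  Tripos types of the bond atoms with an sp³–sp³ fallback
  (k = 0.2, n = 3, φ₀ = 0).

Parameter values shipped (all overridable per scenario):

| class | A | B | C | D | well | clash weight |
|---|---|---|---|---|---|---|
| steric (plp, chemplp) | 3.4 | 3.6 | 4.5 | 5.5 | −0.4 | 20 |
| steric (plp95) | 3.2 | 3.8 | 4.6 | 6.0 | −0.4 | 20 |
| polar pair | 2.3 | 2.6 | 3.1 | 3.4 | −2.0 | 20 |

H-bond: weight −3.0, ideal H···A distance 1.9 Å (tolerance 0.45 Å), ideal
D–H···A angle 180° (tolerance 60°). These magnitudes are this package's own
parameterization: the published functional forms are reproduced, the
published fitted constants are not, so absolute scores are not comparable to
other programs — orderings and term structure are the contract. plp and
chemplp share their steric classes by construction, which is what makes
"chemplp − plp = H-bond term" an exact decomposition here; whether the
original programs share parameters that way is not documented, and we state
the assumption rather than rely on it.

Hydrogens enter only H-bond geometry, never steric sums. The receptor is
fully rigid; receptor hydrogen-position optimization, explicit waters, metal
terms and interaction fingerprints are out of scope.

## Colony optimizer

Per iteration, each of `n_ants` ants samples interval `ℓ` of dof `i` with
probability `τ_iℓ / Σ_k τ_ik`, then draws uniformly inside the interval; the
pose is refined by Nelder–Mead and the iteration-best refined solution
deposits. The update is the single line
`τ_iℓ(t+1) = (1−ρ) τ_iℓ(t) + 1_iℓ Δτ`, with `Δτ = |f(s)|` if `f(s) < 0`
else 0, and the indicator window `[z_{ℓ−3}, z_{ℓ+2}]` (intervals ℓ−2…ℓ+2,
wrapping) for rotational dofs and `[z_{ℓ−2}, z_{ℓ+1}]` (intervals ℓ−1…ℓ+1,
clipped) otherwise. The windows are interval-denominated: on partitions with
few intervals they cover most of the axis and the trail carries little
information — the scheme presumes fine partitions (the canonical one is 1°).

Design choices that the update rule leaves open:

* **Deposit ant**: only the iteration best deposits (MAX-MIN lineage).
* **Trail bounds**: `τ_max = Δτ_best-so-far / ρ`, `τ_min = τ_max / (2 n_i)`,
  refreshed each update and applied by clamping; initial trails sit at an
  optimistic constant `τ₀ = 1` with `τ₀`-based bounds until the first
  deposit. With `ρ = 0` the bounds stay at their τ₀ values.
* **σ (aco_sigma)**: scales the initial simplex edge per dof,
  `σ (b_i − a_i) / n_i` (one interval width × σ). The refined point is
  wrapped (rotational) or clipped (translational) before every evaluation,
  so `f(s) ≤ f(x)` always holds and bounds are respected.
* **Iteration budget**: `ceil(base_iterations / search_speed)` with
  `base_iterations = 100`; early stop after 15 stagnant iterations. This
  makes evaluation counts scale inversely with the speed setting, the
  hardware-independent counterpart of per-ligand docking time.
* **Discrete mode**: with local search disabled, ants evaluate interval
  *midpoints* instead of uniform draws. The search then ranges over exactly
  the cells an exhaustive grid enumerates, so the grid minimum is a true
  lower bound and "found the optimum cell" is well defined. This mode exists
  for oracle comparisons and very fast screens.
* **Restart**: optionally (`restart_after`), trails reinitialize to a
  uniform optimistic level after that many stagnant iterations, keeping the
  global best — the classic MAX-MIN escape from premature convergence. It is
  off by default (the early stop governs) and on in the oracle-comparison
  tests, where premature lock-in onto shallow contact basins is otherwise
  the dominant failure mode of the separable trail model on needle-like
  landscapes.
* **Determinism**: per-ant RNG substreams are seeded by (seed, iteration,
  ant), so results are bit-reproducible and independent of scheduling.

## Defaults table

`aco_ants` is 20 for every combination; the other defaults depend on
(scoring function, search speed): chemplp — speed 4: ρ = 0.15, σ = 0.25;
speed 2: ρ = 0.20, σ = 0.5; speed 1: ρ = 0.20, σ = 1.25; plp speed 4:
ρ = 0.2, σ = 0.5; plp95 speed 4: ρ = 0.2, σ = 1.25. Combinations outside
this table raise a configuration error rather than guessing; explicit
scenario settings always win.

## File formats

MOL2 is the native format (MOLECULE/ATOM/BOND record sets, SMALL,
USER_CHARGES; coordinates and charges written to 4 decimals, which is the
round-trip precision). PDBQT is read as atoms + charges + AutoDock types;
since it carries no bond table, conversion runs bond perception — atoms bond
iff `d ≤ 1.2 (r_cov_i + r_cov_j)` on Cordero covalent radii, never H–H, with
C–O contacts under 1.28 Å promoted to double bonds so carbonyls survive —
followed by rule-based Tripos typing from element, bond orders and neighbor
counts. Input protonation and tautomers are taken verbatim; no enumeration.
The PDBQT BRANCH tree is recorded but torsions are always recomputed by the
package's own rotatable-bond rule, keeping one source of truth.

## Synthetic fixtures

The generator emulates, at desk scale, the inputs a screening campaign
needs; it makes no attempt at chemical realism beyond what the code paths
require.

* **Ligands**: five templates (butane, isopentane, N-methylacetamide,
  propan-1-ol, 3-chloroaniline) with approximate but perception-stable
  geometry, randomized by rigid rotation, ±0.02 Å coordinate jitter and
  ±0.01 e charge jitter (3 decimals, exactly representable in both formats).
  They exercise sp³/sp²/aromatic typing, amide exclusion, torsions, donors
  and acceptors — not ring flexibility, charge models or stereochemistry.
* **Toy complexes**: a ligand is posed near a random cell midpoint of the
  complex's grid (default: 1 Å translation cells, one full-circle interval
  per angle — orientation is handled continuously by sampling and simplex
  refinement, translations carry the trail learning). Pocket pseudo-atoms
  are placed in the steric well around random ligand heavy atoms, at least
  `A + 0.1` Å from all of them and 2 Å apart, plus one acceptor oxygen on a
  donor H axis at ideal H-bond geometry. Generation verifies the planted
  pose scores negative, beats 20 poses displaced ≥ 2 Å, and is the grid's
  distinct optimum cell (no competing non-neighbor cell within 70% of its
  depth); failing seeds are discarded, up to 10 attempts.
* **Libraries**: meta-tranche/tranche/collection trees of tar archives (or
  plain directories) with a manifest as the single source of expected ids;
  collections replicate an identical compound set by default, mirroring
  replicated-collection screening-library layouts. Requests above 10⁴
  compounds are refused — large libraries are generated in chunks at run
  time, never stored.

Because the fixtures are built around planted optima, passing tests show the
machinery is self-consistent (search finds what scoring prefers; formats
round-trip; orchestration is deterministic). They do not show docking
accuracy on real proteins, which depends on fitted scoring constants and
prepared structures outside this package's scope.

## Problem sizes

The shipped tests and benchmarks use deliberately small instances: toy
receptors of ~25 pseudo-atoms, rigid 8-heavy-atom ligands, grids of a few
thousand cells (the exhaustive oracle refuses > 10⁶), fixture libraries of
≤ 24 compounds, and benchmark grids of 6–20 ligands with reduced iteration
budgets. Evaluation counts, not wall seconds, are the asserted cost measure;
wall times are reported as information only.

## Known limitations

* Scoring constants are unfitted; absolute scores have no physical calibration.
* Bond perception is distance-only; unusual geometries can mis-bond, and
  bond-order inference is limited to short C–O contacts.
* Tripos typing covers the common organic subset; exotic atoms fall back to
  the bare element symbol.
* The separable pheromone model learns nothing across correlated dofs;
  coupled landscapes rely on the simplex refinement (or restarts in discrete
  mode).
* The screening layer parallelizes with threads; throughput gains depend on
  how much time is spent in vectorized scoring.
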
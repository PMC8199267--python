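# antdock

Ant-colony protein–ligand docking with piece-wise linear scoring, plus the
virtual-screening orchestration to run it over hierarchical compound
libraries.

`antdock` is aimed at people who want a small, fully inspectable docking
stack: computational chemists prototyping scoring or search ideas, and
developers of screening pipelines who need a deterministic, pure-Python
engine to test orchestration logic (library traversal, format conversion,
consensus scoring, ranking) end to end.

## The method

A docking pose of a flexible ligand is a vector
`x = (t_x, t_y, t_z, α, β, γ, φ_1 … φ_k)`: a translation of the ligand
centroid inside a spherical binding site, a Z–Y–Z Euler orientation, and one
torsion per rotatable bond. Docking is global minimization of a score `f(x)`;
the more negative the score, the stronger the predicted binding.

**Search.** Each degree of freedom `i` is discretized into intervals
`[z_{iℓ−1}, z_iℓ]`. A pheromone trail `τ_iℓ` per interval drives a colony of
ants: an ant picks interval `ℓ` of dof `i` with probability

    p_iℓ = τ_iℓ / Σ_k τ_ik

draws a value inside it, and refines the pose by Nelder–Mead simplex local
search to a local minimizer `s`. After each iteration the trails evaporate,
`τ_iℓ ← (1−ρ) τ_iℓ`, and the iteration-best ant deposits `Δτ = |f(s)|` (when
`f(s) < 0`) on a small window of intervals around each of its components.
Trails are clamped between running MAX-MIN bounds so no interval ever becomes
unreachable.

**Scoring.** Three empirical functions, `plp`, `plp95`, `chemplp`, share a
piece-wise linear receptor–ligand potential per heavy-atom pair (linear clash
penalty below `A`, flat well on `[B, C]`, zero beyond `D`), a repulsive-only
intramolecular clash term over ligand atom pairs ≥ 4 bonds apart, and a
cosine torsional potential `k(1 + cos(nφ − φ_0))`. `chemplp` adds
angle-dependent hydrogen bonds: weight × block(distance deviation) ×
block(angle deviation), ChemScore-style. The numeric parameter values are
this package's own, documented in `docs/methods.md` and overridable per
scenario.

**Screening.** A control file names a ligand library (MOL2, or PDBQT with
on-the-fly conversion to MOL2), one or more docking scenarios and a worker
count. Every ligand in the meta-tranche/tranche/collection hierarchy is
docked under every scenario; the consensus score is the mean of the
per-scenario scores; outputs are partitioned into result and log trees by
filename patterns. Per-ligand seeds make rankings independent of worker
count and traversal order.

## Worked example

Generate a synthetic pocket complex with a known planted pose, then dock:

```sh
$ antdock fixtures make-complex --seed 7 --out .
planted pose scores -37.4789; files in .

$ cat > config.txt <<'EOF'
scoring_function chemplp
search_speed 4
bindingsite_center 0.0 0.0 0.0
bindingsite_radius 4.0
angular_step 360
linear_step 1.0
EOF

$ antdock dock --receptor receptor.mol2 --ligand ligand.mol2 \
    --config config.txt --seed 42 --out pose.mol2
best score: -38.4226 (70500 evaluations, 25 iterations)
wrote pose to pose.mol2
```

The generator plants a pose scoring −37.48 (verified at generation to beat
any pose displaced by ≥ 2 Å). The colony — 25 iterations of 20 ants at
search speed 4, defaults resolved as evaporation 0.15 and simplex scale
0.25 — recovers that basin and the simplex refinement improves on the
planted score slightly (−38.42). `pose.mol2` holds the refined ligand
coordinates.

A screen is driven the same way from a control file
(`antdock screen --control control.txt`), and `antdock report --ranking
ranking.csv --top 100` prints the mean score of the top-ranked compounds
(AVE100). `antdock benchmark run` reproduces the ten-scenario parameter
variation grid (speeds 1/2/4, ant counts 10/50, evaporation 0.10/0.25,
simplex scale 1, plp/plp95) at desk scale.

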
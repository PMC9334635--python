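# cavity-demix

Modelling and analysis of **entropy-driven demixing of DNA molecules in
shallow elliptical nanocavities**.

When two long dsDNA coils — or a long chain and a small plasmid — are
trapped together in a cavity whose height (~200 nm) is far below its width
(~2 µm), excluded-volume entropy alone organizes them: two equal chains
displace each other into an opposed pair, and as the cavity eccentricity
*e* grows they lock onto the poles of the ellipse, swapping ends only by
rare thermally activated barrier crossings. A plasmid sharing the cavity
with a large chain is expelled onto a ring between the chain and the wall
and, at high *e*, onto the poles — a minimal physical picture for nucleoid
occlusion and the polar clustering of high-copy-number plasmids in
bacteria.

This package implements the full computational chain for such experiments,
with synthetic-data generators standing in for the microscope:

* **geometry** — the constant-area ellipse family: semi-axes
  `A = r₀(1−e²)^(−1/4)`, `B = r₀(1−e²)^(+1/4)`, boundary discretization,
  effective radial coordinate `r_eff = √(x²/A² + y²/B²)`.
* **meanfield** — the chain concentration `ρ(r) = (N/h)ψ²(r)` from the
  ground-state-dominance (Gross–Pitaevskii-type) problem
  `−(a_k²/6)∇²ψ + gψ³ = λψ`, `ψ = 0` on the wall, solved with
  boundary-fitted finite differences and semi-implicit imaginary time.
* **potentials** — the plasmid landscape `U_p = aρ + ∮ u(|r_s − r|) ds`
  (exponential or WCA wall kernel), its Boltzmann map
  `P ∝ exp(−U_p/k_BT)`, and the 2 k_BT wall-range diagnostic.
* **model_fit** — recovery of `(a, b, r_b)` by maximizing the cosine
  similarity between model and observed 50 nm position histograms.
* **landscape_dynamics** — overdamped Brownian dynamics
  `dr = −D∇F dt + √(2D dt) η` on `F = −log P` landscapes.
* **trajectory_analysis** — centroid tracking, `P`/`F` maps, the
  separation-vector order parameter `S = 2⟨cos²φ − ½⟩`, pole-swap and
  pole-dwell statistics with single/double-exponential fits, per-axis MSD
  exponents, and contour-averaged density profiles for crowding studies.
* **synthetic_data** — coupled-Langevin "two-blob" surrogates of chain
  pairs, exact Boltzmann position sampling, crowding emulation, and
  PSF-rendered noisy two-channel movies.
* **pipeline** / `cavity-demix` CLI — configuration-driven orchestration
  of generate → track → histogram → fit → simulate → dwell/msd/crowding.

## Worked example

Two chains in cavities of growing eccentricity
(`python examples/05_two_chain_demixing.py`):

```
e = 0.0: S_align = -0.02, swaps = 332, mean dwell =   2.8 s (n = 324)
e = 0.6: S_align =  0.36, swaps = 170, mean dwell =   5.3 s (n = 162)
e = 0.9: S_align =  0.85, swaps =   9, mean dwell =  37.2 s (n = 3)
```

`S_align ≈ 0` is free Brownian rotation of the displaced pair; at
`e = 0.9` the separation vector is locked onto the major axis
(`S_align → 1`) and pole swaps become rare, with the mean dwell time
growing as the waist narrows — the Kramers trend `τ ~ exp(ΔF/k_BT)`.

The plasmid side of the model
(`python examples/03_plasmid_distribution.py`):

```
wall potential reaches 2 kBT at 190 nm from the boundary
plasmid probability peaks on a ring at r = 0.60 um (centre/max = 0.88)
```

The ring marks the segregation zone between wall repulsion and chain
exclusion; `examples/04_fit_recovery.py` recovers the generating
parameters from sampled positions, and `examples/06_subdiffusion_msd.py`
shows the landscape-induced sub-diffusion (`α_∥ ≈ 0.88`, `α_⊥ ≈ 0.40` at
`e = 0.9`).

## Documentation

`docs/methods.md` describes the model, its assumptions, the numerical
choices, what the synthetic generators do and do not emulate, and the
package's known limitations.
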
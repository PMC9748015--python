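# sticklat

Lattice sticker-and-spacer Monte Carlo simulations and condensate
analyses for prion-like low-complexity domains (PLCDs).

PLCDs such as the hnRNPA1 low-complexity domain phase-separate through
phase separation coupled to percolation: aromatic stickers (Tyr, Phe)
form reversible physical crosslinks while spacers set solvation
preferences, so a density transition (dilute/dense coexistence) is
coupled to a connectivity transition (a condensate-spanning network).
`sticklat` is a desk-scale toolkit for studying this coupling with a
single-bead-per-residue model on a periodic cubic lattice:

* **Model** — sequences are reduced to ten residue types
  (Y, F, R, K, G, S, T, Q, N and a generic X) with a symmetric
  pairwise contact-energy table ε(a, b) over sites within √3 lattice
  units (the 26-site neighborhood).  A mean-field adjustment can scale
  attractions in proportion to the net charge per residue (NCPR)
  difference from a reference sequence.  A synthetic default table is
  packaged; users supply their own fitted table as TSV.
* **Sampling** — Metropolis Monte Carlo (acceptance
  min[1, exp(−ΔE/k_BT)], k_B = 1, dimensionless T) with local
  single-bead and co-local moves, reptation, chain translation and
  cluster translation; a local-only mode makes attempted moves a
  usable proxy for time.
* **Phase analyses** — per-chain dense/dilute assignment via the
  largest connected cluster; binodals c_dilute(T), c_dense(T); the
  two-phase width ω = log₁₀(c_dilute/c_dense); the ERMSL
  10^RMS(log₁₀ c_sim/c_exp) for comparing dilute arms (1 = perfect
  overlay, 10 = order-of-magnitude error); the swelling ratio
  α = √⟨R²_g,dense⟩/√⟨R²_g,dilute⟩ and its master curve
  α = 1 + exp[−a(ω − b)]; ternary contact fractions
  f_intra + f_inter + f_sol = 1; the overlap fraction φ* = N r³/R_e³.
* **Network analyses** — condensate graphs (chains as nodes, edges for
  inter-chain sticker–sticker contacts), unnormalized betweenness
  centrality, mean path length L and clustering coefficient C with
  Erdős–Rényi references (log n/log⟨k⟩ and ⟨k⟩/n), centrality
  dynamics, the ratio of association g_a, and discrete-Weibull fits
  P(s) = 1 − exp[−((s+1)/λ)^k] to sticker-cluster sizes.
* **Interface analyses** — radial density profiles in 1/4-l.u. shells
  with an exact lattice-site prior, hyperbolic-tangent interface fits
  in log₁₀ density returning (φ′, φ″, r_mid, Δ), crosslinks per
  sticker, radial R_g/asphericity/local-extension profiles, distinct
  chains per residue, cos²θ chain orientation, and the Δ_p ~ N^0.45
  interface-width scaling machinery.
* **Fixtures** — deterministic generators with known ground truth
  (planted tanh-profile droplets, planted-hub and Watts–Strogatz
  graphs, discrete-Weibull samples, binodal arm pairs with known
  offset, sticker-spacer sequences with controlled patterning).

## Worked example

```python
import sticklat as sk
from sticklat.fixtures import generate_sequence

model = sk.default_contact_model()
seq = generate_sequence(30, sticker_fraction=0.3, patterning="uniform", seed=0)

traj = sk.run_simulation(seq, 120, model, T=55.0, box_side=36,
                         n_sweeps=3000, seed=7, snapshot_interval=150,
                         start="droplet")

from sticklat.phase import measure_phase_point, phase_rg2_samples, swelling_ratio
c_dil, c_den = measure_phase_point(traj, model)
dense, dilute = phase_rg2_samples(traj, model)
alpha = swelling_ratio(dense, dilute).alpha
print(f"c_dilute={c_dil:.2e}  c_dense={c_den:.3f}  alpha={alpha:.3f}")

g = sk.build_condensate_graph(traj.configuration(-1), model)
s = sk.small_world_summary(g)
print(f"n={s.n}  L/L_ER={s.L_ratio:.2f}  C/C_ER={s.C_ratio:.2f}")
```

prints (seed 7):

```
c_dilute=4.40e-04  c_dense=0.377  alpha=1.125
n=120  L/L_ER=1.34  C/C_ER=3.57
```

The dilute and dense volume fractions differ by three orders of
magnitude (ω ≈ −2.9), chains in the dense phase are ~12% larger than
coexisting dilute chains (the swelling signature), and the condensate
graph clusters ~3.6× above a random graph with the same density while
its path lengths stay near-random — the small-world fingerprint of a
physically crosslinked condensate.

The same pipeline is exposed as a CLI
(`sticklat simulate | binodal | swelling | graph | interface |
fixtures | report`); see `sticklat --help`.

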
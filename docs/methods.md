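# Methods

This note documents the model, the numerical choices, and the
assumptions behind `sticklat`, including what the synthetic fixtures
do and do not emulate.

## Model

**Reduced alphabet.** Sequences over the 20 standard amino acids are
reduced to ten residue types: Y, F, R, K, G, S, T, Q, N, and a generic
X for everything else.  Tyr and Phe are the stickers (the
`sticker_mask`); arginine can act as an auxiliary sticker purely
through its contact energies and is never flagged in the mask, so all
sticker-resolved analyses (crosslinks, clusters, graph edges, g_a)
concern aromatics only.  NCPR is computed from the raw sequence with
R/K = +1, D/E = −1 and histidine and cysteine neutral (the standard
pH-7 convention).

**Contacts.** All distances use minimum image in a periodic cubic box.
"Within √3 lattice units" on an integer lattice is exactly the 26-site
Chebyshev-1 neighborhood, which is used uniformly for contact
energies, bonds, graph edges, sticker clusters and crosslinks.  Two
conventions about bonded (consecutive) residues:

* the energy function, crosslink counts, g_a tallies and sticker
  clusters **exclude** bonded pairs — a crosslink is a contact that
  could dissociate;
* the solvation census behind f_intra/f_inter/f_sol **includes** them,
  because the three categories must partition all 26 neighbor sites of
  every bead for the fractions to sum to 1 exactly.

**Contact energies.** A symmetric 10×10 table in simulation energy
units with k_B = 1 and dimensionless temperature; the physically
calibrated window for PLCD-like tables is T ∈ [40, 60].  The packaged
default table (`data/contact_energies_synthetic_default.tsv`) is a
constructed stand-in, not a fitted model: it encodes the sticker
hierarchy |ε_YY| > |ε_YF| > |ε_FF| > |ε_R-aromatic|, near-inert
lysine, and a Y-Y → Y-K swap gap of 18.95 energy units (0.47 k_BT at
T = 40, 0.32 k_BT at T = 60).  Fitted tables are supplied as TSV
through `read_energy_table`, which verifies symmetry to 1e−9.

**NCPR adjustment.** The mean-field charge correction weakens every
attractive entry additively by κ·|NCPR − NCPR_ref|.  Both κ (default
0, i.e. disabled) and the reference NCPR (default 0) are configuration
parameters: the published magnitude of the proportionality constant is
not available to this implementation, so the rule ships inert and
overridable rather than with a guessed strength.

## Monte Carlo engine

Metropolis sampling with acceptance min[1, exp(−ΔE/T)].  Moves:

| move      | default weight | notes |
|-----------|---------------|-------|
| local     | 1.0   | one bead to a vacant neighbor site, bond-checked |
| colocal   | 0.3   | a bonded pair translated by one offset |
| reptation | 0.2   | slithering snake; the heteropolymer sequence stays attached to bead indices, so the chain energy is recomputed |
| chain     | 0.05  | rigid whole-chain translation by a unit offset |
| cluster   | 0.005 | rigid translation of a maximal connected chain cluster |

All proposals are symmetric.  Cluster moves reject any translation
that would create a contact with an outside bead (the no-merge rule;
because the cluster is maximal there are no outside contacts before
the move either, so ΔE = 0 and detailed balance is preserved), and
abort early when the cluster exceeds half the chains — translating a
system-spanning droplet relaxes nothing and would dominate runtime.
"Local-only" mode (local + colocal) is required by all analyses that
use attempted moves as a proxy for time (RMSD, centrality persistence,
contact lifetimes).

Bond lengths are constrained to the same ≤ √3 neighborhood
(bond-fluctuation-style).  Excluded volume is one bead per site.
Energies are tracked incrementally; the drift against a full
recomputation stays below 1e−9 over 10⁶ moves (tested).  Equilibrium
sampling is verified against exhaustive Boltzmann enumeration on a
dimer system small enough to enumerate, and against the self-avoiding
walk exponent for athermal chains.

**Equilibration.** `run_simulation` marks the first half of stored
frames as equilibration (configurable); `energy_stationarity` provides
a split-half check (mean difference vs 2 pooled SE) on what remains.
Analyses consume `Trajectory.equilibrated()` frames.

**Apparent scaling exponent.** `single_chain_nu` regresses
log ⟨R²(s)⟩^½ on log s for internal distances.  Defaults: separations
s ∈ [2, N/3] and a 20% end margin (pairs with either residue in the
outer fifth of the chain are excluded).  End segments are
systematically less swollen and depress the apparent exponent at
desk-scale N; with the interior window, athermal chains of N = 64
reproduce ν = 0.588 ± 0.02 across replicates.  Collapsed-globule
scaling (ν → 1/3) is probed via R_g(N) across chain lengths, because
internal distances saturate at the globule diameter.

## Phase analyses

**Phase assignment** clusters chains by any-bead contact; the largest
connected cluster is the dense phase.  A dispersed system (largest
cluster = 1 chain) is flagged degenerate.  The stability heuristic for
binodal points requires the largest cluster to hold ≥ 25% of chains
and ≥ 5 chains.

**Dense/dilute concentrations.**  The dense-phase volume convention is
genuinely ambiguous for small systems, so two estimators ship:

* `region` — beads of dense-labeled chains divided by the volume of
  their occupied sites dilated by 1 l.u.  Assumption-free, but biased
  low for small droplets whose fringe dominates the dilated volume
  (roughly −45% on an ~800-chain planted droplet; tested).
* `profile` — the plateaus of the tanh fit to the radial density
  profile.  Unbiased by fringe geometry (recovers planted plateaus to
  a few percent) but requires a single droplet with a resolvable
  interface.

Both are logged; binodal assembly uses `region` by default.

**ERMSL.** 10^RMS(log₁₀ c_sim/c_exp) over temperature-matched points;
exact temperature matches are preferred and log-linear interpolation
in T is used otherwise; non-overlapping grids are rejected.  The two
anchor identities (identical arms → 1, uniform 10× offset → 10) hold
exactly and pin down the base-10 antilog-of-RMS form.

**Swelling.** α uses root-mean-square R_g per phase (not the mean of
R_g).  The master curve α = 1 + exp[−a(ω − b)] is fitted by nonlinear
least squares initialized from the log-linearization; on noise-free
synthetic data the printed constants (a = 0.33, b = −9.5) are
recovered to 1e−6.  The critical temperature is never extrapolated;
ω is the only closeness-to-criticality coordinate used anywhere.

## Network analyses

Condensate graphs take the largest connected chain cluster as the node
set, with edges for inter-chain sticker–sticker adjacency.
Betweenness is unnormalized and uses the undirected (unordered-pair)
convention; pass `ordered=True` for the doubled ordered-pair
convention.  L is the mean shortest path over unordered pairs, C the
mean local clustering coefficient; the Erdős–Rényi references are
log n/log⟨k⟩ and ⟨k⟩/n with no finite-size correction (valid while
⟨k⟩ ≪ n).  All three metrics are verified against exhaustive
enumeration on graphs with n ≤ 12.

Top-central chains are the top 5% by betweenness; ties at the cutoff
break deterministically by chain id.  Sticker clusters are connected
components of nonbonded sticker–sticker contacts (intra- and
inter-chain).  Per-sticker cluster-size probabilities weight each
cluster by its size; the discrete-Weibull parameters come from
weighted least squares on the linearized CDF
ln[−ln(1 − P(s))] vs ln(s + 1), with residual outliers beyond 3 scaled
MADs removed and one refit.  Exact CDF points are recovered to 1e−9;
10⁵ sampled sizes recover (λ, k) within 5%.

## Interface analyses

Radial shells are 1/4 l.u. wide around the condensate center of mass,
which is computed from dense-phase beads with per-axis circular means
(periodic-safe).  Density divides per-shell bead counts by the exact
per-shell lattice-site count for the periodic cube (cached per box
and center).  Before fitting, shells are adaptively pooled so every
fitted point holds ≥ 10 beads: fitting the log density of sparse
shells conditional on their being nonempty biases the dilute plateau
upward (this mattered at desk scale; pooled fits recover planted
dilute densities within ~10%).  The tanh model is fitted in log₁₀
density with per-point σ ∝ 1/√count, initialized from the profile
endpoints, the half-log crossing and the 25–75% span; the interface
band is r_mid ± Δ/2.  Profiles with < 0.5 decades of dynamic range are
rejected as non-sigmoidal rather than fitted.

Asphericity uses the normalized gyration-tensor form
[(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] / [2(λ₁+λ₂+λ₃)²] ∈ [0, 1] (0 =
sphere, 1 = rod), consistent with a ~0.4 threshold for cigar-like
shapes; the normalization is switchable if a different convention is
needed.  R_g and asphericity profiles are bead-weighted (each bead
contributes its chain's value to its own shell); local extension bins
the |i−j| = 5 distance by the first residue's shell; orientation
computes cos²θ between the end-to-end segment and the end-to-center
segment, once per chain end, binned by that end's shell.

**Desk-scale caveat for interfacial R_g.**  With droplet radii only
~4× the chain R_g, bead-weighted binning inflates the apparent dense
plateau (chains reaching the droplet center are a large-R_g-biased
sample), and the R_g *mean* over the fitted band does not exceed the
plateau mean even though the shell-resolved profile clearly peaks in
the interfacial region.  The interfacial-expansion signature is
therefore asserted as: the peak of the 1-l.u.-coarsened radial R_g
profile within [r_mid − Δ, r_mid + Δ] (shells with ≥ 20 observations)
exceeds both the dense-plateau mean and the far-dilute mean.  At full
scale the band mean itself shows the effect.

**Width scaling.**  Δ_p per chain length is the mean Δ over the low-T
plateau (maximal low-T run with |dΔ/dT| below a slope threshold,
default 0.1 l.u. per T unit); the exponent comes from log–log
regression of Δ_p on N.  Synthetic Δ_p ∝ N^0.45 inputs round-trip the
exponent to 1e−9; the full homopolymer campaign behind the published
0.45 is cluster-scale and out of desk reach.

## Synthetic fixtures

Every generator is seed-deterministic and returns its ground truth.
The droplet generator plants a tanh radial density by deficit-driven
placement: per-shell bead targets are computed from the requested
profile, chain start shells are pre-committed by multinomial sampling
of the initial target distribution (sampling the evolving deficit
would funnel late chains into the sparse tail), and growth steps are
steered toward shells still in deficit, decrementing bead by bead.
Realized profiles recover planted parameters to within counting noise
(Δ within ~5–10%, r_mid within 0.5 l.u., plateaus within ~10%).  The
fixture is a statistical construction, not a physical configuration:
its chains have no equilibrium conformational statistics, no
energy-consistent contact network, and no capillary fluctuations, so
passing fixture-based tests validates the measurement machinery, not
the physics.  Physics signatures are always tested on genuine MC
trajectories.

Weibull samples invert the discrete CDF on support s ≥ 1; binodal
pairs apply an exact log₁₀ offset (optionally with log-normal jitter);
generated sequences place an exact sticker count with uniform, blocky
or random patterning over a G/S spacer background (uniform patterning
mimics the conserved aromatic spacing of PLCDs).

## Study conditions for the scaled-down physics checks

Full-scale campaigns (10⁴ chains of 137 residues in 120³ boxes, 31
variants) are cluster-scale; the packaged checks run desk-scale
systems chosen once as follows: a uniform-patterned synthetic sequence
(length 30, sticker fraction 0.3) at 120 chains in a 36³ box for the
swelling analyses, T ∈ {55, 62, 70} — at these chain lengths the
dilute arm is empty below T ≈ 55, and above T ≈ 80 the largest-cluster
phase assignment degrades as the system nears one phase; a 40-mer at
200 chains in 44³ at T = 60 for interface-resolved profiles; 220
10-mers in 28³ at T = 40 for condensate-graph topology; and 3000–4000
sweeps from a pre-formed droplet start, analyzing the second half.
These sizes reproduce the qualitative signatures (dense-phase chain
expansion, α → 1 as ω → 0, interfacial R_g peak and radial
orientation, C/C_ER ≥ 3) with margins documented in the test suite.

## Known limitations

* The move inventory is this package's own; other lattice engines use
  different inventories and frequencies, which changes dynamics (not
  equilibrium averages).
* The NCPR adjustment ships disabled pending a calibrated constant.
* `region`-method concentrations are biased low for small droplets
  (see above); prefer the `profile` method when a clean droplet
  exists.
* Dynamics analyses (lifetimes, persistence, RMSD) treat the frame
  interval as the time unit and require local-only trajectories;
  contact lifetimes are lower bounds when runs extend past the last
  frame.
* No anisotropic bonding, off-lattice geometry, or rheological
  inference; unit conversions to Kelvin/molar are user-supplied
  configuration constants and are never computed.
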
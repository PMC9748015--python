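"""Phase behaviour: coexistence curves, two-phase width, ERMSL,
swelling ratio, contact fractions and the overlap concentration.

Conventions
-----------
Concentrations are volume fractions (occupied lattice sites over total
sites in the region).  The two-phase width is
``omega(T) = log10(c_dilute / c_dense)``, negative inside the binodal
and approaching 0 at criticality.  The swelling ratio
``alpha = sqrt(<Rg^2>_dense) / sqrt(<Rg^2>_dilute)`` collapses onto the
master curve ``alpha = 1 + exp(-a (omega - b))`` across variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .contacts import chain_cluster_labels, neighbor_census
from .mc import OFFSETS26, LatticeConfiguration, Trajectory
from .sequences import ContactModel


# ---------------------------------------------------------------------------
# Phase assignment
# ---------------------------------------------------------------------------

@dataclass
class PhaseLabels:
    """Per-chain phase assignment: True = dense, False = dilute."""

    dense: np.ndarray
    largest_cluster_size: int
    degenerate: bool  # largest "cluster" is a single chain

    @property
    def n_dense(self) -> int:
        return int(self.dense.sum())

    @property
    def n_dilute(self) -> int:
        return int((~self.dense).sum())


def assign_phases(config: LatticeConfiguration,
                  model: ContactModel | None = None) -> PhaseLabels:
    """Label each chain dense or dilute.

    Chains are clustered by any-bead contact within the interaction
    range; the largest connected cluster (and by construction every
    chain in contact with it) is the dense phase, all other chains are
    dilute.  A fully dispersed system yields a degenerate size-1
    "largest cluster" and is flagged.
    """
    labels = chain_cluster_labels(config)
    sizes = np.bincount(labels)
    big = int(sizes.argmax())
    dense = labels == big
    return PhaseLabels(
        dense=dense,
        largest_cluster_size=int(sizes.max()),
        degenerate=bool(sizes.max() <= 1),
    )


def is_phase_separated(labels: PhaseLabels, n_chains: int,
                       min_fraction: float = 0.25, min_chains: int = 5) -> bool:
    """Stability heuristic: one distinct dense cluster holding at least
    ``min_fraction`` of the chains (and at least ``min_chains``)."""
    return (labels.largest_cluster_size >= min_chains
            and labels.largest_cluster_size >= min_fraction * n_chains)


# ---------------------------------------------------------------------------
# Binodal
# ---------------------------------------------------------------------------

@dataclass
class PhasePoint:
    T: float
    c_dilute: float
    c_dense: float
    se_dilute: float = 0.0
    se_dense: float = 0.0
    n_replicates: int = 1

    def __post_init__(self):
        if not (0 <= self.c_dilute <= self.c_dense <= 1):
            raise ValueError(
                f"need 0 <= c_dilute <= c_dense <= 1, got "
                f"({self.c_dilute}, {self.c_dense})"
            )

    @property
    def omega(self) -> float:
        return two_phase_width(self)


@dataclass
class Binodal:
    points: list[PhasePoint]
    sequence_id: str = ""

    def __post_init__(self):
        ts = [p.T for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("temperatures must be strictly increasing")

    def dilute_arm(self) -> list[tuple[float, float]]:
        return [(p.T, p.c_dilute) for p in self.points]

    def dense_arm(self) -> list[tuple[float, float]]:
        return [(p.T, p.c_dense) for p in self.points]


def two_phase_width(point: PhasePoint) -> float:
    """omega = log10(c_dilute / c_dense); negative below criticality."""
    if point.c_dilute <= 0:
        raise ValueError("two-phase width undefined for zero dilute concentration")
    return math.log10(point.c_dilute / point.c_dense)


def dense_region_mask(config: LatticeConfiguration,
                      labels: PhaseLabels) -> np.ndarray:
    """Dense-phase region: sites of dense-chain beads dilated by 1 l.u.
    (Chebyshev ball), periodic."""
    mask = np.zeros((config.box_side,) * 3, dtype=bool)
    dense_beads = labels.dense[config.chain_of]
    p = config.positions[dense_beads]
    mask[p[:, 0], p[:, 1], p[:, 2]] = True
    out = mask.copy()
    for o in OFFSETS26:
        out |= np.roll(mask, shift=tuple(o), axis=(0, 1, 2))
    return out


def measure_phase_point(
    traj: Trajectory,
    model: ContactModel,
    frames: list[int] | None = None,
    method: str = "region",
) -> tuple[float, float] | None:
    """(c_dilute, c_dense) averaged over frames; None if never separated.

    Two estimators are provided because the dense-phase volume
    convention is genuinely ambiguous for small systems:

    ``method="region"``
        c_dense = beads of dense-labeled chains / volume of their
        occupied sites dilated by 1 l.u.; c_dilute = remaining beads /
        remaining volume.  Simple and assumption-free but biased low
        for small droplets, whose fringe dominates the dilated volume.
    ``method="profile"``
        the plateaus (phi'', phi') of the tanh fit to the radial
        density profile.  Requires a single droplet with a resolvable
        interface; unbiased by fringe geometry.
    """
    if frames is None:
        frames = traj.equilibrated()
    if method == "profile":
        from .interface import (average_profiles, condensate_center,
                                fit_interface, radial_density_profile)
        profiles = []
        for fi in frames:
            cfg = traj.configuration(fi)
            labels = assign_phases(cfg, model)
            if not is_phase_separated(labels, cfg.n_chains):
                continue
            center = condensate_center(cfg, labels)
            profiles.append(radial_density_profile(
                cfg, center=center, require_single_droplet=False))
        if not profiles:
            return None
        fit = fit_interface(average_profiles(profiles, count_weighted=False))
        return float(fit.phi_dilute), float(fit.phi_dense)
    if method != "region":
        raise ValueError(f"unknown method {method!r}")
    dil, den = [], []
    for fi in frames:
        cfg = traj.configuration(fi)
        labels = assign_phases(cfg, model)
        if not is_phase_separated(labels, cfg.n_chains):
            continue
        region = dense_region_mask(cfg, labels)
        v_dense = int(region.sum())
        v_dilute = cfg.volume - v_dense
        dense_beads = int(labels.dense[cfg.chain_of].sum())
        dilute_beads = cfg.n_beads - dense_beads
        if v_dense == 0 or v_dilute == 0:
            continue
        den.append(dense_beads / v_dense)
        dil.append(dilute_beads / v_dilute)
    if not dil:
        return None
    return float(np.mean(dil)), float(np.mean(den))


def compute_binodal(
    trajectories_by_T: dict[float, list[Trajectory]],
    model: ContactModel,
    sequence_id: str = "",
) -> Binodal:
    """Assemble a binodal from replicate trajectories keyed by T.

    Non-separated state points are excluded with a warning.  Standard
    errors are across replicates.
    """
    points = []
    for T in sorted(trajectories_by_T):
        vals = []
        for traj in trajectories_by_T[T]:
            r = measure_phase_point(traj, model)
            if r is not None:
                vals.append(r)
        if not vals:
            warnings.warn(f"T={T}: no stable phase separation; point excluded")
            continue
        arr = np.array(vals)
        n = len(vals)
        se = arr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(2)
        points.append(PhasePoint(
            T=float(T), c_dilute=float(arr[:, 0].mean()),
            c_dense=float(arr[:, 1].mean()),
            se_dilute=float(se[0]), se_dense=float(se[1]), n_replicates=n,
        ))
    return Binodal(points=points, sequence_id=sequence_id)


# ---------------------------------------------------------------------------
# ERMSL
# ---------------------------------------------------------------------------

def _match_arms(sim_arm, exp_arm):
    sim = sorted((float(t), float(c)) for t, c in sim_arm)
    exp = sorted((float(t), float(c)) for t, c in exp_arm)
    if any(c <= 0 for _, c in sim + exp):
        raise ValueError("ERMSL requires strictly positive concentrations")
    exp_t = np.array([t for t, _ in exp])
    exp_logc = np.log10([c for _, c in exp])
    lo, hi = max(sim[0][0], exp_t[0]), min(sim[-1][0], exp_t[-1])
    pairs = []
    for t, c in sim:
        exact = np.nonzero(np.isclose(exp_t, t))[0]
        if len(exact):
            pairs.append((math.log10(c), float(exp_logc[exact[0]])))
        elif lo <= t <= hi and len(exp) > 1:
            pairs.append((math.log10(c), float(np.interp(t, exp_t, exp_logc))))
    if not pairs:
        raise ValueError("ERMSL: no overlapping temperature range between arms")
    return np.array(pairs)


def ermsl(sim_arm, exp_arm) -> float:
    """Exponential root-mean-square log discrepancy between two arms.

    ``10 ** RMS(log10(c_sim / c_exp))`` over temperature-matched points
    (exact matches preferred, log-linear interpolation otherwise).
    1 means the arms overlay perfectly; 10 means an average
    order-of-magnitude discrepancy.
    """
    pairs = _match_arms(sim_arm, exp_arm)
    d = pairs[:, 0] - pairs[:, 1]
    return float(10 ** math.sqrt(float(np.mean(d**2))))


# ---------------------------------------------------------------------------
# Swelling ratio and master curve
# ---------------------------------------------------------------------------

@dataclass
class SwellingResult:
    alpha: float
    mean_rg2_dense: float
    mean_rg2_dilute: float
    n_dense: int
    n_dilute: int
    omega: float | None = None


def swelling_ratio(dense_rg2, dilute_rg2) -> SwellingResult:
    """alpha = sqrt(<Rg^2>_dense) / sqrt(<Rg^2>_dilute) (RMS form)."""
    dense_rg2 = np.asarray(dense_rg2, dtype=float)
    dilute_rg2 = np.asarray(dilute_rg2, dtype=float)
    if dense_rg2.size == 0 or dilute_rg2.size == 0:
        raise ValueError("swelling ratio needs nonempty samples in both phases")
    md, mi = float(dense_rg2.mean()), float(dilute_rg2.mean())
    return SwellingResult(
        alpha=math.sqrt(md / mi), mean_rg2_dense=md, mean_rg2_dilute=mi,
        n_dense=dense_rg2.size, n_dilute=dilute_rg2.size,
    )


def phase_rg2_samples(
    traj: Trajectory, model: ContactModel, frames: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-chain Rg^2 samples split by phase over equilibrated frames."""
    if frames is None:
        frames = traj.equilibrated()
    dense_vals, dilute_vals = [], []
    for fi in frames:
        cfg = traj.configuration(fi)
        labels = assign_phases(cfg, model)
        for c in range(cfg.n_chains):
            (dense_vals if labels.dense[c] else dilute_vals).append(cfg.chain_rg2(c))
    return np.array(dense_vals), np.array(dilute_vals)


def master_curve(omega, a, b):
    """alpha = 1 + exp(-a (omega - b))."""
    return 1.0 + np.exp(-a * (np.asarray(omega, dtype=float) - b))


def fit_master_curve(points) -> tuple[float, float]:
    """Least-squares fit of the swelling master curve to (omega, alpha).

    Initialized from the linearization ln(alpha - 1) = -a omega + a b,
    then refined by nonlinear least squares.  Requires >= 4 points with
    alpha > 1 somewhere (otherwise ill-conditioned).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 4:
        raise ValueError("master-curve fit needs >= 4 (omega, alpha) points")
    om, al = pts[:, 0], pts[:, 1]
    if np.all(al <= 1):
        raise ValueError("master-curve fit ill-conditioned: alpha <= 1 everywhere")
    pos = al > 1
    slope, intercept = np.polyfit(om[pos], np.log(al[pos] - 1.0), 1)
    a0 = -slope if slope < 0 else 0.3
    b0 = intercept / a0 if a0 else 0.0
    popt, _ = curve_fit(master_curve, om, al, p0=(a0, b0), maxfev=20000)
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Ternary contact fractions
# ---------------------------------------------------------------------------

@dataclass
class ContactFractions:
    """Per-chain neighbor-census fractions (sum to 1 exactly)."""

    f_intra: np.ndarray
    f_inter: np.ndarray
    f_sol: np.ndarray
    rg: np.ndarray
    chain_ids: np.ndarray


def contact_fractions(
    config: LatticeConfiguration,
    model: ContactModel | None = None,
    dense_only: bool = True,
) -> ContactFractions:
    """Neighbor census per chain: intra-chain, inter-chain and solvent
    (empty) fractions of the 26 neighbor sites of every bead, summed
    over the chain and normalized so f_intra + f_inter + f_sol = 1.
    """
    same, other = neighbor_census(config)
    if dense_only:
        labels = assign_phases(config, model)
        chains = np.nonzero(labels.dense)[0]
    else:
        chains = np.arange(config.n_chains)
    fi, fe, fs, rg, ids = [], [], [], [], []
    for c in chains:
        sl = config.chain_slice(c)
        s = int(same[sl].sum())
        o = int(other[sl].sum())
        total = 26 * config.chain_lens[c]
        e = int(total - s - o)
        fi.append(s / total)
        fe.append(o / total)
        fs.append(e / total)
        rg.append(math.sqrt(config.chain_rg2(c)))
        ids.append(c)
    return ContactFractions(
        f_intra=np.array(fi), f_inter=np.array(fe), f_sol=np.array(fs),
        rg=np.array(rg), chain_ids=np.array(ids, dtype=np.int64),
    )


def ternary_bins(fracs: ContactFractions, n_bins: int = 20):
    """Bin chains on the (f_intra, f_inter, f_sol) simplex; mean Rg per bin.

    Returns a dict mapping (i, j) integer bin coordinates (for f_intra
    and f_inter; f_sol is implied) to (mean Rg, count).
    """
    out: dict[tuple[int, int], list[float]] = {}
    bi = np.minimum((fracs.f_intra * n_bins).astype(int), n_bins - 1)
    bj = np.minimum((fracs.f_inter * n_bins).astype(int), n_bins - 1)
    for i, j, r in zip(bi, bj, fracs.rg):
        out.setdefault((int(i), int(j)), []).append(float(r))
    return {k: (float(np.mean(v)), len(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Overlap concentration
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    phi_star: float
    N: int
    r: float
    Re: float

    def regime(self, phi_sat: float, tie: str = "dilute") -> str:
        """'dilute' when phi_sat < phi*, else 'semi-dilute'; exact ties
        fall to ``tie``."""
        if phi_sat < self.phi_star:
            return "dilute"
        if phi_sat == self.phi_star:
            return tie
        return "semi-dilute"


def overlap_fraction(N: int, r: float, Re: float) -> OverlapResult:
    """Overlap volume fraction phi* = N r^3 / Re^3.

    ``Re`` is the root-mean-square end-to-end distance; apply to
    dilute-phase chains (for the full-length PLCD model, N = 137 and
    r = 0.5 lattice units).
    """
    if N <= 0 or r <= 0 or Re <= 0:
        raise ValueError("N, r, Re must all be positive")
    return OverlapResult(phi_star=N * r**3 / Re**3, N=int(N), r=float(r), Re=float(Re))
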
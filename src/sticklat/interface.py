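"""Radial condensate structure and interface analysis.

All radial statistics bin values into spherical shells of width 1/4
lattice unit around the condensate center of mass (computed with
circular-mean unwrapping so a droplet straddling the periodic boundary
is handled exactly).  Density profiles divide per-shell bead counts by
the exact number of lattice sites in each shell for the given periodic
cube, and the dilute/dense transition is fitted with a hyperbolic
tangent in log10 density:

    log10 phi(r) = (log10 phi'' + log10 phi')/2
                 - (log10 phi'' - log10 phi')/2 * tanh(2 (r - r_mid)/Delta)

yielding the coexisting densities phi' (dilute) and phi'' (dense), the
interface midpoint r_mid and the interfacial width Delta.  The
interface band is reported as [r_mid - Delta/2, r_mid + Delta/2].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit

from .contacts import nonbonded_pairs, chain_cluster_labels
from .mc import LatticeConfiguration
from .phase import assign_phases, PhaseLabels

SHELL_WIDTH = 0.25


# ---------------------------------------------------------------------------
# Center, shells and the exact lattice prior
# ---------------------------------------------------------------------------

def condensate_center(config: LatticeConfiguration,
                      labels: PhaseLabels | None = None) -> np.ndarray:
    """Center of mass of dense-phase beads, periodic-safe.

    Uses the circular mean per axis: each coordinate is mapped to an
    angle on [0, 2 pi), averaged as a unit vector, and mapped back.
    """
    if labels is None:
        labels = assign_phases(config)
    beads = labels.dense[config.chain_of]
    p = config.positions[beads]
    if len(p) == 0:
        raise ValueError("no dense-phase beads: center undefined")
    box = config.box_side
    theta = 2 * math.pi * p / box
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return (mean_angle / (2 * math.pi) * box) % box


@lru_cache(maxsize=8)
def _shell_site_counts(box: int, center_key: tuple[float, float, float]) -> np.ndarray:
    center = np.array(center_key)
    g = np.arange(box, dtype=float)
    d = np.empty((box, box, box))
    dx = np.abs(g - center[0]); dx = np.minimum(dx, box - dx)
    dy = np.abs(g - center[1]); dy = np.minimum(dy, box - dy)
    dz = np.abs(g - center[2]); dz = np.minimum(dz, box - dz)
    d = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                + dz[None, None, :] ** 2)
    n_shells = int(math.ceil(d.max() / SHELL_WIDTH)) + 1
    idx = np.minimum((d / SHELL_WIDTH).astype(int), n_shells - 1)
    return np.bincount(idx.ravel(), minlength=n_shells)


def shell_site_counts(box: int, center: np.ndarray) -> np.ndarray:
    """Exact per-shell lattice-site counts (the volume prior) for a
    periodic cube; sums to box^3.  Center is rounded to 1/8 l.u. for
    caching."""
    key = tuple(np.round(np.asarray(center, dtype=float) * 8) / 8)
    return _shell_site_counts(int(box), key)


def radial_distances(config: LatticeConfiguration, center: np.ndarray,
                     positions: np.ndarray | None = None) -> np.ndarray:
    p = config.positions if positions is None else positions
    box = config.box_side
    d = np.abs(p - center)
    d = np.minimum(d, box - d)
    return np.sqrt((d**2).sum(axis=1))


@dataclass
class RadialProfile:
    """Per-shell statistic: shell i covers [i, i+1) * SHELL_WIDTH.

    Density profiles additionally carry ``prior``, the exact number of
    lattice sites per shell, so that shells can be re-pooled without
    bias (pooled density = summed counts / summed site prior).
    """

    edges: np.ndarray       # len n_shells + 1
    value: np.ndarray       # per-shell value (nan where undefined)
    count: np.ndarray       # observations per shell
    se: np.ndarray          # standard error per shell (nan where undefined)
    prior: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def rebin_low_count_shells(profile: RadialProfile,
                           min_count: int = 10):
    """Merge consecutive density shells until each merged bin holds at
    least ``min_count`` beads.

    Returns (r, phi, n) arrays for the merged bins, with phi = summed
    counts / summed site prior and r the prior-weighted bin centroid.
    Conditioning a log density on "at least one bead seen" biases
    sparse shells upward; pooling them removes that selection bias
    while leaving well-populated shells untouched.  Requires a profile
    with a site prior.
    """
    if profile.prior is None:
        raise ValueError("rebinning requires a density profile with a prior")
    rs, phis, ns = [], [], []
    c_acc = p_acc = rp_acc = 0.0
    for r, c, p in zip(profile.centers, profile.count, profile.prior):
        if p <= 0:
            continue
        c_acc += c
        p_acc += p
        rp_acc += r * p
        if c_acc >= min_count:
            rs.append(rp_acc / p_acc)
            phis.append(c_acc / p_acc)
            ns.append(c_acc)
            c_acc = p_acc = rp_acc = 0.0
    if p_acc > 0 and c_acc > 0:
        rs.append(rp_acc / p_acc)
        phis.append(c_acc / p_acc)
        ns.append(c_acc)
    return np.array(rs), np.array(phis), np.array(ns)


def _profile_from_samples(r: np.ndarray, values: np.ndarray,
                          n_shells: int) -> RadialProfile:
    idx = np.minimum((r / SHELL_WIDTH).astype(int), n_shells - 1)
    count = np.bincount(idx, minlength=n_shells).astype(float)
    tot = np.bincount(idx, weights=values, minlength=n_shells)
    tot2 = np.bincount(idx, weights=values**2, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = tot / count
        var = tot2 / count - mean**2
        se = np.sqrt(np.maximum(var, 0) / np.maximum(count, 1))
    se[count < 2] = np.nan
    edges = np.arange(n_shells + 1) * SHELL_WIDTH
    return RadialProfile(edges=edges, value=mean, count=count, se=se)


def _n_shells(box: int) -> int:
    return int(math.ceil(box * math.sqrt(3) / 2 / SHELL_WIDTH)) + 1


def radial_density_profile(
    config: LatticeConfiguration,
    center: np.ndarray | None = None,
    require_single_droplet: bool = True,
) -> RadialProfile:
    """Bead volume fraction per radial shell (count / exact site prior)."""
    labels = assign_phases(config)
    if require_single_droplet:
        lab = chain_cluster_labels(config)
        sizes = np.sort(np.bincount(lab))[::-1]
        if len(sizes) > 1 and sizes[1] >= max(5, 0.5 * sizes[0]):
            raise ValueError(
                "multiple droplets detected; analyze one droplet at a time "
                "(or pass require_single_droplet=False)"
            )
    if center is None:
        center = condensate_center(config, labels)
    n_shells = _n_shells(config.box_side)
    prior = shell_site_counts(config.box_side, center)
    prior = np.pad(prior, (0, max(0, n_shells - len(prior))))[:n_shells]
    r = radial_distances(config, center)
    idx = np.minimum((r / SHELL_WIDTH).astype(int), n_shells - 1)
    count = np.bincount(idx, minlength=n_shells).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = count / prior
    phi[prior == 0] = np.nan
    edges = np.arange(n_shells + 1) * SHELL_WIDTH
    se = np.full(n_shells, np.nan)
    return RadialProfile(edges=edges, value=phi, count=count, se=se,
                         prior=prior.astype(float))


def average_profiles(profiles: list[RadialProfile],
                     count_weighted: bool = True) -> RadialProfile:
    """Pool per-frame radial profiles into one profile.

    With ``count_weighted`` each shell's values are averaged with
    weights equal to the per-frame observation counts (right for
    per-sample statistics); otherwise shells are averaged uniformly
    over the frames where they are defined (right for densities, whose
    per-frame values are already normalized by the site prior).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    n = max(len(p.value) for p in profiles)

    def padded(a, fill=np.nan):
        return np.pad(a.astype(float), (0, n - len(a)), constant_values=fill)

    if all(p.prior is not None for p in profiles):
        # density profiles: pooled density = total counts / total sites
        c = np.array([padded(p.count, 0.0) for p in profiles]).sum(axis=0)
        pr = np.array([padded(p.prior, 0.0) for p in profiles]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(pr > 0, c / np.maximum(pr, 1e-300), np.nan)
        edges = np.arange(n + 1) * SHELL_WIDTH
        return RadialProfile(edges=edges, value=phi, count=c,
                             se=np.full(n, np.nan), prior=pr)

    v = np.array([padded(p.value) for p in profiles])
    c = np.array([padded(p.count, 0.0) for p in profiles])
    w = np.where(np.isnan(v), 0.0, c if count_weighted else 1.0)
    vv = np.where(np.isnan(v), 0.0, v)
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(tot > 0, (vv * w).sum(axis=0) / np.maximum(tot, 1e-300),
                        np.nan)
        var = np.where(
            tot > 0,
            (w * (vv - mean) ** 2).sum(axis=0) / np.maximum(tot, 1e-300),
            np.nan,
        )
    counts = c.sum(axis=0)
    se = np.sqrt(var / np.maximum(len(profiles), 1))
    edges = np.arange(n + 1) * SHELL_WIDTH
    return RadialProfile(edges=edges, value=mean, count=counts, se=se)


# ---------------------------------------------------------------------------
# Interface fit
# ---------------------------------------------------------------------------

@dataclass
class InterfaceFit:
    phi_dilute: float
    phi_dense: float
    r_mid: float
    delta: float
    residual_rms: float

    @property
    def band(self) -> tuple[float, float]:
        return (self.r_mid - self.delta / 2, self.r_mid + self.delta / 2)


def tanh_log_profile(r, log_phi_dense, log_phi_dilute, r_mid, delta):
    r = np.asarray(r, dtype=float)
    mid = 0.5 * (log_phi_dense + log_phi_dilute)
    amp = 0.5 * (log_phi_dense - log_phi_dilute)
    return mid - amp * np.tanh(2.0 * (r - r_mid) / delta)


def fit_interface(profile: RadialProfile, min_decades: float = 0.5,
                  weight_by_counts: bool = True) -> InterfaceFit:
    """Nonlinear least squares of the tanh interface model in log10
    density.  Rejects profiles whose dynamic range is below
    ``min_decades`` (flat, no interface to fit).

    With ``weight_by_counts`` (default) shells are weighted by their
    bead counts via sigma ~ 1/sqrt(count): the sampling variance of a
    log density is inversely proportional to the number of beads
    observed in the shell, so the nearly empty innermost shells no
    longer distort the dense plateau.  Weighting leaves noise-free
    profiles fitted exactly.

    Profiles that carry a site prior are first adaptively rebinned so
    every fitted point holds >= 10 beads: fitting the log density of
    sparse shells conditional on being nonempty would bias the dilute
    plateau upward.
    """
    if profile.prior is not None:
        r, phi, n_obs = rebin_low_count_shells(profile, min_count=10)
        ok = phi > 0
        r, y = r[ok], np.log10(phi[ok])
        sigma = 1.0 / np.sqrt(n_obs[ok] + 1.0) if weight_by_counts else None
    else:
        ok = np.isfinite(profile.value) & (profile.value > 0)
        r = profile.centers[ok]
        y = np.log10(profile.value[ok])
        sigma = None
        if weight_by_counts and np.all(np.isfinite(profile.count[ok])):
            sigma = 1.0 / np.sqrt(profile.count[ok] + 1.0)
    if len(r) < 6:
        raise ValueError("too few populated shells for an interface fit")
    head = float(np.median(y[:4]))
    tail = float(np.median(y[-4:]))
    if head - tail < min_decades:
        raise ValueError(
            f"profile not sigmoidal: log10 density range {head - tail:.3f} "
            f"< {min_decades} decades"
        )
    y_mid = 0.5 * (head + tail)
    below = np.nonzero(y < y_mid)[0]
    r_mid0 = float(r[below[0]]) if len(below) else float(r[len(r) // 2])
    y25 = head - 0.25 * (head - tail)
    y75 = head - 0.75 * (head - tail)
    r25 = float(r[np.argmin(np.abs(y - y25))])
    r75 = float(r[np.argmin(np.abs(y - y75))])
    delta0 = max(abs(r75 - r25), SHELL_WIDTH)
    popt, _ = curve_fit(
        tanh_log_profile, r, y, sigma=sigma,
        p0=(head, tail, r_mid0, delta0),
        bounds=([-np.inf, -np.inf, 0, SHELL_WIDTH / 10],
                [np.inf, np.inf, float(r[-1]), np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=50000,
    )
    resid = y - tanh_log_profile(r, *popt)
    fit = InterfaceFit(
        phi_dilute=10.0 ** popt[1], phi_dense=10.0 ** popt[0],
        r_mid=float(popt[2]), delta=float(popt[3]),
        residual_rms=float(np.sqrt((resid**2).mean())),
    )
    if fit.phi_dilute >= fit.phi_dense:
        raise ValueError("fit inverted: phi_dilute >= phi_dense")
    return fit


# ---------------------------------------------------------------------------
# Radially resolved statistics
# ---------------------------------------------------------------------------

def crosslinks_per_sticker_profile(
    config: LatticeConfiguration,
    center: np.ndarray | None = None,
) -> tuple[RadialProfile, RadialProfile, RadialProfile]:
    """Sticker-sticker crosslinks per sticker vs distance from center.

    Returns (total, intra, inter) profiles; total = intra + inter
    exactly.  A crosslink is a nonbonded sticker-sticker contact.
    """
    if center is None:
        center = condensate_center(config)
    st = config.sticker_mask
    n = config.n_beads
    intra = np.zeros(n)
    inter = np.zeros(n)
    i, j = nonbonded_pairs(config)
    keep = st[i] & st[j]
    i, j = i[keep], j[keep]
    same = config.chain_of[i] == config.chain_of[j]
    for arr, m in ((intra, same), (inter, ~same)):
        np.add.at(arr, i[m], 1.0)
        np.add.at(arr, j[m], 1.0)
    sel = np.nonzero(st)[0]
    r = radial_distances(config, center, config.positions[sel])
    n_shells = _n_shells(config.box_side)
    return (
        _profile_from_samples(r, intra[sel] + inter[sel], n_shells),
        _profile_from_samples(r, intra[sel], n_shells),
        _profile_from_samples(r, inter[sel], n_shells),
    )


def asphericity(gyration_tensor: np.ndarray) -> float:
    """Normalized gyration-tensor asphericity in [0, 1].

    ((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / (2 (l1+l2+l3)^2); 0 for a
    sphere, 1 for a rod; values above ~0.4 indicate cigar-shaped
    conformations.
    """
    lam = np.linalg.eigvalsh(gyration_tensor)
    tr = lam.sum()
    if tr == 0:
        return 0.0
    num = ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
           + (lam[2] - lam[0]) ** 2)
    return float(num / (2 * tr**2))


def chain_property_profile(
    config: LatticeConfiguration,
    prop: str,
    center: np.ndarray | None = None,
    delta_seq: int = 5,
) -> RadialProfile:
    """Radial profile of a per-chain conformational property.

    ``prop`` is one of ``"rg"``, ``"asphericity"`` or
    ``"local_extension"``.  For rg/asphericity every bead contributes
    its chain's value to the bead's own shell (bead-weighted, so a
    chain straddling shells is split in proportion to its beads).  For
    local extension the distance between residue pairs separated by
    exactly ``delta_seq`` along the chain is binned by the first
    residue's shell; chains shorter than delta_seq + 1 are skipped.
    """
    if center is None:
        center = condensate_center(config)
    n_shells = _n_shells(config.box_side)
    rs, vals = [], []
    if prop in ("rg", "asphericity"):
        for c in range(config.n_chains):
            if prop == "rg":
                v = math.sqrt(config.chain_rg2(c))
            else:
                v = asphericity(config.gyration_tensor(c))
            p = config.chain_positions(c)
            r = radial_distances(config, center, p)
            rs.append(r)
            vals.append(np.full(len(p), v))
    elif prop == "local_extension":
        for c in range(config.n_chains):
            if config.chain_lens[c] < delta_seq + 1:
                continue
            u = config.unwrapped_chain(c)
            d = np.linalg.norm(u[delta_seq:] - u[:-delta_seq], axis=1)
            p = config.chain_positions(c)[:-delta_seq]
            rs.append(radial_distances(config, center, p))
            vals.append(d)
    else:
        raise ValueError(f"unknown property {prop!r}")
    if not rs:
        raise ValueError("no chains eligible for the requested property")
    return _profile_from_samples(
        np.concatenate(rs), np.concatenate(vals), n_shells
    )


def distinct_chains_per_residue(
    config: LatticeConfiguration,
    center: np.ndarray | None = None,
) -> RadialProfile:
    """Per shell: distinct chains with >= 1 bead in the shell divided by
    the number of beads in the shell (in (0, 1]); empty shells are
    masked as nan."""
    if center is None:
        center = condensate_center(config)
    n_shells = _n_shells(config.box_side)
    r = radial_distances(config, center)
    idx = np.minimum((r / SHELL_WIDTH).astype(int), n_shells - 1)
    n_b = np.bincount(idx, minlength=n_shells).astype(float)
    pairs = np.unique(np.stack([idx, config.chain_of], axis=1), axis=0)
    n_c = np.bincount(pairs[:, 0], minlength=n_shells).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = n_c / n_b
    val[n_b == 0] = np.nan
    edges = np.arange(n_shells + 1) * SHELL_WIDTH
    return RadialProfile(edges=edges, value=val, count=n_b,
                         se=np.full(n_shells, np.nan))


def orientation_profile(
    config: LatticeConfiguration,
    center: np.ndarray | None = None,
) -> RadialProfile:
    """Mean cos^2 of the angle between a chain's end-to-end segment and
    the segment from an end bead to the condensate center.

    Each chain contributes twice, once per end bead, binned by that end
    bead's shell.  An isotropic ensemble averages to 1/3; values near 1
    mean chains point along the radius (perpendicular to the
    interface), values near 0 mean they wrap around it.  Chains with a
    zero end-to-end vector are excluded.
    """
    if center is None:
        center = condensate_center(config)
    box = config.box_side
    n_shells = _n_shells(config.box_side)
    rs, vals = [], []
    for c in range(config.n_chains):
        if config.chain_lens[c] < 2:
            continue
        u = config.unwrapped_chain(c)
        e2e = u[-1] - u[0]
        if not e2e.any():
            continue
        for end in (0, -1):
            p = config.chain_positions(c)[end].astype(float)
            v = center - p
            v -= box * np.round(v / box)
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            cos = float(np.dot(e2e, v)) / (np.linalg.norm(e2e) * nv)
            rs.append(float(np.linalg.norm(
                np.minimum(np.abs(p - center), box - np.abs(p - center))
            )))
            vals.append(cos**2)
    if not rs:
        raise ValueError("no chains with a nonzero end-to-end vector")
    return _profile_from_samples(
        np.array(rs), np.array(vals), n_shells
    )


# ---------------------------------------------------------------------------
# Interface width scaling with chain length
# ---------------------------------------------------------------------------

def detect_plateau(series, slope_threshold: float = 0.1) -> list[int]:
    """Indices of the low-T plateau of a Delta(T) series.

    The plateau is the maximal run starting at the lowest temperature
    over which |dDelta/dT| stays below ``slope_threshold``.
    """
    pts = sorted((float(t), float(d)) for t, d in series)
    if len(pts) < 2:
        raise ValueError("need >= 2 temperatures")
    idx = [0]
    for i in range(1, len(pts)):
        dT = pts[i][0] - pts[i - 1][0]
        if abs((pts[i][1] - pts[i - 1][1]) / dT) < slope_threshold:
            idx.append(i)
        else:
            break
    if len(idx) < 2:
        raise ValueError(f"no low-T plateau detected; Delta(T) series: {pts}")
    return idx


def interface_width_scaling(
    fits_by_length: dict[int, list[tuple[float, float]]],
    slope_threshold: float = 0.1,
) -> tuple[dict[int, float], float]:
    """Plateau widths Delta_p per chain length and their scaling exponent.

    ``fits_by_length`` maps chain length N to a (T, Delta) series.
    Returns ({N: Delta_p}, exponent) where the exponent comes from a
    log-log regression of Delta_p against N (~0.45 at full scale).
    """
    if len(fits_by_length) < 3:
        raise ValueError("need >= 3 chain lengths")
    plateaus = {}
    for N, series in fits_by_length.items():
        pts = sorted(series)
        idx = detect_plateau(pts, slope_threshold)
        plateaus[int(N)] = float(np.mean([pts[i][1] for i in idx]))
    Ns = np.array(sorted(plateaus))
    dp = np.array([plateaus[int(n)] for n in Ns])
    slope, _ = np.polyfit(np.log(Ns.astype(float)), np.log(dp), 1)
    return plateaus, float(slope)
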
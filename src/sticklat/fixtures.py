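"""Synthetic fixtures with known ground truth.

Each generator is deterministic under a fixed seed and returns its
ground-truth parameters alongside the data, so every analysis stage
can be exercised without running simulations: lattice droplets with a
planted tanh density profile, graphs with planted bridge hubs,
Watts-Strogatz small-world calibration graphs, discrete-Weibull
cluster-size samples, binodal arm pairs with a known log offset, and
sticker-spacer sequences with controlled patterning.

The droplet generator uses density-weighted chain growth followed by
legality checks; it is a statistical fixture, not a physical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .interface import tanh_log_profile
from .mc import OFFSETS26, LatticeConfiguration
from .sequences import EncodedSequence, encode_sequence


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible fixture request: kind, parameters and seed."""

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


_GENERATORS = {}


def generate(spec: FixtureSpec):
    try:
        fn = _GENERATORS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return fn(seed=spec.seed, **spec.parameters)


def _register(kind):
    def deco(fn):
        _GENERATORS[kind] = fn
        return fn
    return deco


# ---------------------------------------------------------------------------
# Droplet with a planted tanh radial profile
# ---------------------------------------------------------------------------

@_register("droplet")
def make_droplet_config(
    box: int,
    phi_dilute: float,
    phi_dense: float,
    r_mid: float,
    delta: float,
    chain_length: int = 4,
    seed: int = 0,
) -> tuple[LatticeConfiguration, dict[str, float]]:
    """Lattice configuration whose expected shell density follows the
    tanh interface model with the given parameters.

    Chains are grown with per-site acceptance weighted by the target
    density, so the realized profile matches the planted one up to
    counting noise and a slight smearing by the chain extent (keep
    ``chain_length`` small relative to ``delta``).  Returns the legal
    configuration and the ground-truth parameter dict.
    """
    if not 0 < phi_dilute < phi_dense <= 1:
        raise ValueError("need 0 < phi_dilute < phi_dense <= 1")
    if r_mid + delta >= box / 2 * math.sqrt(3):
        raise ValueError("droplet does not fit in the box")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2 - 0.5)
    g = np.arange(box, dtype=float)
    dx = np.abs(g - center[0]); dx = np.minimum(dx, box - dx)
    dist = np.sqrt(dx[:, None, None] ** 2 + dx[None, :, None] ** 2
                   + dx[None, None, :] ** 2)
    p_site = 10.0 ** tanh_log_profile(
        dist, math.log10(phi_dense), math.log10(phi_dilute), r_mid, delta
    )
    expected_beads = float(p_site.sum())
    n_chains = max(1, int(round(expected_beads / chain_length)))

    # Deficit-driven placement: track, per 1/4-l.u. radial shell, how many
    # beads are still owed relative to the planted expectation, and steer
    # both chain starts and growth steps toward shells in deficit.  This
    # self-corrects the radial histogram so the realized profile matches
    # the planted one to counting noise despite chain connectivity.
    shell_w = 0.25
    shell_of = (dist / shell_w).astype(np.int64)
    n_shells = int(shell_of.max()) + 1
    deficit = np.zeros(n_shells)
    np.add.at(deficit, shell_of.ravel(), p_site.ravel())
    sites_by_shell = [np.flatnonzero(shell_of.ravel() == s) for s in range(n_shells)]

    occ = np.zeros((box, box, box), dtype=bool)
    occ_flat = occ.ravel()
    positions = np.empty((n_chains * chain_length, 3), dtype=np.int64)
    # Start shells are pre-committed by sampling the *initial* target
    # distribution: sampling the evolving deficit instead would funnel
    # every late chain into the sparse tail once the dense core fills.
    p_start = deficit / deficit.sum()
    start_shells = rng.choice(len(deficit), size=n_chains, p=p_start)
    bead = 0
    for ci in range(n_chains):
        chain = None
        shell = int(start_shells[ci])
        for _attempt in range(500):
            chain = _grow_targeted(box, chain_length, occ, occ_flat, shell_of,
                                   deficit, sites_by_shell, rng, shell)
            if chain is not None:
                break
            shell = int(rng.choice(len(deficit), p=p_start))
        if chain is None:
            raise ValueError("droplet fixture infeasible at requested densities")
        for q in chain:
            occ[q[0], q[1], q[2]] = True
        positions[bead:bead + chain_length] = chain
        bead += chain_length

    seq = encode_sequence("Y" + "G" * (chain_length - 1), id="droplet_chain") \
        if chain_length > 1 else encode_sequence("Y", id="droplet_chain")
    cfg = LatticeConfiguration(
        box, positions,
        np.full(n_chains, chain_length, dtype=np.int64),
        [seq], np.zeros(n_chains, dtype=np.int64),
    )
    cfg.validate()
    truth = {
        "phi_dilute": phi_dilute, "phi_dense": phi_dense,
        "r_mid": r_mid, "delta": delta, "center": center,
        "n_chains": n_chains,
    }
    return cfg, truth


def _grow_targeted(box, L, occ, occ_flat, shell_of, deficit, sites_by_shell,
                   rng, shell):
    # start site uniform among the start shell's vacancies.  Deficits
    # are decremented bead by bead during growth so a single chain
    # cannot overfill a low-target (dilute) shell; on a dead end they
    # are restored.
    sites = sites_by_shell[shell]
    vacant = sites[~occ_flat[sites]]
    if len(vacant) == 0:
        return None
    cur = np.array(np.unravel_index(vacant[rng.integers(len(vacant))],
                                    occ.shape), dtype=np.int64)
    chain = [cur]
    taken = {tuple(cur)}
    deficit[shell] -= 1.0
    used = [shell]
    for _ in range(L - 1):
        cands = (cur + OFFSETS26) % box
        wts = []
        keep = []
        for q in cands:
            t = tuple(q)
            if t in taken or occ[t]:
                continue
            wts.append(max(deficit[shell_of[t]], 0.0))
            keep.append(q)
        if not keep:
            for s in used:  # dead end: restore and retry
                deficit[s] += 1.0
            return None
        wts = np.array(wts)
        if wts.sum() <= 0:
            # all local shells at/over target: hug the least-saturated
            # direction instead of wandering into the dilute tail
            raw = np.array([deficit[shell_of[tuple(q)]] for q in keep])
            wts = raw - raw.min() + 1e-9
        cur = keep[rng.choice(len(keep), p=wts / wts.sum())]
        chain.append(cur)
        taken.add(tuple(cur))
        s = shell_of[tuple(cur)]
        deficit[s] -= 1.0
        used.append(s)
    return np.array(chain, dtype=np.int64)


# ---------------------------------------------------------------------------
# Graph fixtures
# ---------------------------------------------------------------------------

@_register("planted_hub_graph")
def make_planted_hub_graph(
    n: int, n_hubs: int, seed: int = 0, p_intra: float = 0.5
) -> tuple[nx.Graph, list[int]]:
    """Random communities bridged exclusively by planted hub nodes.

    Nodes 0..n_hubs-1 are hubs; the remaining nodes form n_hubs + 1
    dense Erdos-Renyi communities, and community i talks to community
    i+1 only through hub i.  Every shortest path between the
    communities crosses a hub, so hubs are guaranteed the top
    betweenness ranks.
    """
    if n_hubs < 1 or n <= 3 * n_hubs + 3:
        raise ValueError("need n > 3 * n_hubs + 3 and n_hubs >= 1")
    rng = np.random.default_rng(seed)
    others = list(range(n_hubs, n))
    comms = np.array_split(others, n_hubs + 1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for comm in comms:
        comm = list(comm)
        for i in range(len(comm)):
            for j in range(i + 1, len(comm)):
                if rng.random() < p_intra:
                    g.add_edge(comm[i], comm[j])
        # make sure each community is internally connected
        for a, b in zip(comm[:-1], comm[1:]):
            g.add_edge(a, b)
    for h in range(n_hubs):
        for comm in (comms[h], comms[h + 1]):
            comm = list(comm)
            picks = rng.choice(len(comm), size=min(3, len(comm)), replace=False)
            for p in picks:
                g.add_edge(h, comm[p])
    return g, list(range(n_hubs))


@_register("ws_graph")
def make_ws_graph(n: int, k: int, p: float, seed: int = 0) -> nx.Graph:
    """Watts-Strogatz graph for small-world calibration (k even, k < n)."""
    if k % 2 or k >= n:
        raise ValueError("need k even and k < n")
    return nx.connected_watts_strogatz_graph(n, k, p, seed=int(seed))


# ---------------------------------------------------------------------------
# Weibull samples, binodal pairs, sequences
# ---------------------------------------------------------------------------

@_register("weibull_sample")
def sample_weibull_clusters(
    lam: float, k: float, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Per-sticker cluster sizes (>= 1) whose CDF follows the discrete
    Weibull form 1 - exp(-((s+1)/lambda)^k), sampled by inversion."""
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and k must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    s = np.ceil(lam * (-np.log1p(-u)) ** (1.0 / k) - 1.0).astype(np.int64)
    return np.maximum(s, 1)


@_register("binodal_pair")
def make_binodal_pair(
    base_arm, log10_offset: float, jitter_sd: float = 0.0, seed: int = 0
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Two dilute arms whose true ERMSL is 10^|log10_offset|.

    Optional log-normal jitter (``jitter_sd`` in log10 units) emulates
    measurement noise on the second arm.
    """
    rng = np.random.default_rng(seed)
    base = [(float(t), float(c)) for t, c in base_arm]
    noise = rng.normal(0.0, jitter_sd, size=len(base)) if jitter_sd else \
        np.zeros(len(base))
    shifted = [
        (t, c * 10.0 ** (log10_offset + e)) for (t, c), e in zip(base, noise)
    ]
    return base, shifted


@_register("sequence")
def generate_sequence(
    length: int,
    sticker_fraction: float,
    patterning: str = "uniform",
    seed: int = 0,
    id: str | None = None,
) -> EncodedSequence:
    """Sticker-spacer sequence with an exact sticker count.

    ``patterning``: "uniform" spaces the Y stickers evenly along the
    chain (the PLCD-like arrangement), "blocky" packs them into one
    contiguous block, "random" scatters them.  Spacers alternate G/S.
    """
    if not 0 < sticker_fraction < 1:
        raise ValueError("sticker_fraction must be in (0, 1)")
    n_stick = int(round(length * sticker_fraction))
    n_stick = max(1, min(length - 1, n_stick))
    rng = np.random.default_rng(seed)
    if patterning == "uniform":
        pos = np.round(np.linspace(0, length - 1, n_stick)).astype(int)
    elif patterning == "blocky":
        start = (length - n_stick) // 2
        pos = np.arange(start, start + n_stick)
    elif patterning == "random":
        pos = rng.choice(length, size=n_stick, replace=False)
    else:
        raise ValueError(f"unknown patterning {patterning!r}")
    residues = ["G" if i % 2 == 0 else "S" for i in range(length)]
    for p in pos:
        residues[int(p)] = "Y"
    name = id or f"synth_{patterning}_L{length}_f{sticker_fraction:g}"
    return encode_sequence("".join(residues), id=name)
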
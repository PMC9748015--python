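"""Metropolis Monte Carlo engine for sticker-and-spacer lattice polymers.

Chains live on a periodic cubic lattice with single-site excluded
volume.  Bonded (consecutive) beads must stay within sqrt(3) lattice
units of each other, i.e. inside the 26-site neighborhood — the
bond-fluctuation-inspired convention.  Nonbonded beads within the same
neighborhood are "in contact" and contribute the pairwise contact
energy of their residue types.  Sampling follows the Metropolis rule:
a proposed move is accepted with probability min(1, exp(-dE/T)) with
kB = 1 and T dimensionless (the physically interesting window for the
PLCD model is 40 <= T <= 60).

Move inventory (relative attempt frequencies configurable):

* local      — single-bead displacement to a vacant neighboring site
* colocal    — a bonded bead pair translated together by one offset
* reptation  — slithering-snake end move (sequence stays attached to
               bead indices, so the chain energy is recomputed)
* chain      — rigid translation of one whole chain by a unit offset
* cluster    — rigid translation of a maximal connected cluster of
               chains, rejected if it would touch any outside bead
               (the standard no-merge rule, which keeps dE = 0 and
               preserves detailed balance)

"local-only" mode (local + colocal) is what the dynamics analyses
require, where the number of attempted moves serves as a proxy for
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequences import ContactModel, EncodedSequence

# 26 neighbor offsets (Chebyshev distance 1); first 13 are the
# lexicographically positive half used to count unordered pairs once.
_off = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_half = [o for o in _off if o > (0, 0, 0)]
_rest = [o for o in _off if o < (0, 0, 0)]
OFFSETS26 = np.array(_half + _rest, dtype=np.int64)
N_HALF = len(_half)  # 13

MOVE_NAMES = ("local", "colocal", "reptation", "chain", "cluster")


@dataclass(frozen=True)
class MoveSet:
    """Relative attempt frequencies for the five move kinds."""

    local: float = 1.0
    colocal: float = 0.3
    reptation: float = 0.2
    chain: float = 0.05
    cluster: float = 0.005

    def __post_init__(self):
        w = self.weights
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("move frequencies must be nonnegative, not all zero")

    @property
    def weights(self) -> np.ndarray:
        return np.array(
            [self.local, self.colocal, self.reptation, self.chain, self.cluster],
            dtype=float,
        )

    @property
    def cumulative(self) -> np.ndarray:
        w = self.weights
        return np.cumsum(w / w.sum())

    @property
    def local_only(self) -> bool:
        return self.reptation == 0 and self.chain == 0 and self.cluster == 0

    @classmethod
    def local_moves(cls) -> "MoveSet":
        """Local-only move set (single-bead + co-local) for dynamics."""
        return cls(local=1.0, colocal=0.3, reptation=0.0, chain=0.0, cluster=0.0)


class LatticeConfiguration:
    """Per-chain bead coordinates on a periodic cubic lattice.

    Beads are stored chain-contiguously: chain ``c`` owns global bead
    indices ``chain_starts[c] : chain_starts[c] + chain_lens[c]``.
    """

    def __init__(
        self,
        box_side: int,
        positions: np.ndarray,
        chain_lens: np.ndarray,
        sequences: list[EncodedSequence],
        chain_seq_index: np.ndarray | None = None,
    ):
        """``sequences`` lists one EncodedSequence per chain unless
        ``chain_seq_index`` maps chains into a shorter unique list."""
        self.box_side = int(box_side)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.chain_lens = np.asarray(chain_lens, dtype=np.int64)
        self.chain_starts = np.concatenate(
            ([0], np.cumsum(self.chain_lens)[:-1])
        ).astype(np.int64)
        if chain_seq_index is None:
            chain_seq_index = np.arange(len(sequences), dtype=np.int64)
        self.chain_seq_index = np.asarray(chain_seq_index, dtype=np.int64)
        self.sequences = list(sequences)
        if len(self.chain_seq_index) != len(self.chain_lens):
            raise ValueError("one sequence index required per chain")
        types = []
        sticker = []
        chain_of = []
        for c, si in enumerate(self.chain_seq_index):
            seq = self.sequences[si]
            if len(seq) != self.chain_lens[c]:
                raise ValueError(f"chain {c}: length mismatch with sequence {seq.id}")
            types.append(seq.codes)
            sticker.append(seq.sticker_mask)
            chain_of.append(np.full(len(seq), c, dtype=np.int64))
        self.types = np.concatenate(types).astype(np.int8)
        self.sticker_mask = np.concatenate(sticker)
        self.chain_of = np.concatenate(chain_of)
        if self.positions.shape != (self.n_beads, 3):
            raise ValueError("positions must be (n_beads, 3)")

    # -- basic properties ---------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.chain_lens)

    @property
    def n_beads(self) -> int:
        return int(self.chain_lens.sum())

    @property
    def volume(self) -> int:
        return self.box_side**3

    def chain_slice(self, c: int) -> slice:
        s = self.chain_starts[c]
        return slice(s, s + self.chain_lens[c])

    def chain_positions(self, c: int) -> np.ndarray:
        return self.positions[self.chain_slice(c)]

    def sequence_of_chain(self, c: int) -> EncodedSequence:
        return self.sequences[self.chain_seq_index[c]]

    def copy(self) -> "LatticeConfiguration":
        return LatticeConfiguration(
            self.box_side,
            self.positions.copy(),
            self.chain_lens.copy(),
            self.sequences,
            self.chain_seq_index.copy(),
        )

    def occupancy(self) -> np.ndarray:
        """(box,box,box) grid holding bead index + 1, 0 for vacant."""
        occ = np.zeros((self.box_side,) * 3, dtype=np.int64)
        p = self.positions
        occ[p[:, 0], p[:, 1], p[:, 2]] = np.arange(self.n_beads) + 1
        return occ

    # -- geometry helpers ---------------------------------------------------

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement components for the periodic box."""
        b = self.box_side
        return (np.asarray(d) + b // 2) % b - b // 2

    def unwrapped_chain(self, c: int) -> np.ndarray:
        """Chain coordinates unwrapped along the backbone (float array).

        Consecutive beads are within the bond range (< box/2), so
        accumulating minimum-image bond vectors from the first bead
        recovers true metric coordinates.
        """
        p = self.chain_positions(c)
        steps = self.min_image(np.diff(p, axis=0))
        out = np.empty_like(p)
        out[0] = p[0]
        np.cumsum(steps, axis=0, out=out[1:])
        out[1:] += p[0]
        return out.astype(float)

    def chain_com(self, c: int) -> np.ndarray:
        """Center of mass of one chain from unwrapped coordinates
        (may lie outside [0, box))."""
        return self.unwrapped_chain(c).mean(axis=0)

    def chain_rg2(self, c: int) -> float:
        u = self.unwrapped_chain(c)
        return float(((u - u.mean(axis=0)) ** 2).sum(axis=1).mean())

    def chain_end_to_end(self, c: int) -> float:
        u = self.unwrapped_chain(c)
        return float(np.linalg.norm(u[-1] - u[0]))

    def gyration_tensor(self, c: int) -> np.ndarray:
        u = self.unwrapped_chain(c)
        d = u - u.mean(axis=0)
        return d.T @ d / len(d)

    # -- legality audit -----------------------------------------------------

    def validate(self) -> None:
        """Raise if excluded volume, bounds, or bond constraints fail."""
        p = self.positions
        if p.min() < 0 or p.max() >= self.box_side:
            raise ValueError("bead coordinates outside [0, box_side)")
        flat = (p[:, 0] * self.box_side + p[:, 1]) * self.box_side + p[:, 2]
        if len(np.unique(flat)) != self.n_beads:
            raise ValueError("excluded volume violated: duplicate site occupancy")
        for c in range(self.n_chains):
            q = self.chain_positions(c)
            d = np.abs(self.min_image(np.diff(q, axis=0)))
            if d.size and d.max() > 1:
                raise ValueError(f"bond constraint violated in chain {c}")


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _total_energy_kernel(pos, occ, types, chain_of, energies, box, offsets, n_half):
    e = 0.0
    n = pos.shape[0]
    for i in range(n):
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        for k in range(n_half):
            nx = (x + offsets[k, 0]) % box
            ny = (y + offsets[k, 1]) % box
            nz = (z + offsets[k, 2]) % box
            j = occ[nx, ny, nz] - 1
            if j >= 0:
                if chain_of[i] == chain_of[j] and abs(i - j) == 1:
                    continue
                e += energies[types[i], types[j]]
    return e


@njit(cache=True)
def _env_energy(bead, px, py, pz, occ, types, chain_of, energies, box, offsets):
    """Energy of ``bead`` at (px,py,pz) with every occupied neighbor,
    excluding bonded partners.  The bead itself must be absent from occ."""
    e = 0.0
    for k in range(26):
        nx = (px + offsets[k, 0]) % box
        ny = (py + offsets[k, 1]) % box
        nz = (pz + offsets[k, 2]) % box
        j = occ[nx, ny, nz] - 1
        if j >= 0:
            if chain_of[bead] == chain_of[j] and abs(bead - j) == 1:
                continue
            e += energies[types[bead], types[j]]
    return e


@njit(cache=True)
def _cheb_dist(ax, ay, az, bx, by, bz, box):
    h = box // 2
    dx = abs(((ax - bx) + h) % box - h)
    dy = abs(((ay - by) + h) % box - h)
    dz = abs(((az - bz) + h) % box - h)
    return max(dx, max(dy, dz))


@njit(cache=True)
def _chain_energy(c, pos, occ, types, chain_of, chain_starts, chain_lens,
                  energies, box, offsets):
    """Energy of chain ``c``: full weight for inter-chain contacts,
    half weight for intra-chain nonbonded contacts (each intra pair is
    visited from both endpoints)."""
    e = 0.0
    s = chain_starts[c]
    L = chain_lens[c]
    for i in range(s, s + L):
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        for k in range(26):
            nx = (x + offsets[k, 0]) % box
            ny = (y + offsets[k, 1]) % box
            nz = (z + offsets[k, 2]) % box
            j = occ[nx, ny, nz] - 1
            if j >= 0:
                if chain_of[j] == c:
                    if abs(i - j) == 1:
                        continue
                    e += 0.5 * energies[types[i], types[j]]
                else:
                    e += energies[types[i], types[j]]
    return e


@njit(cache=True)
def _run_mc(pos, occ, types, chain_of, chain_starts, chain_lens, sticker,
            energies, box, T, n_moves, cum_probs, seed, offsets,
            attempts, accepts):
    """Attempt ``n_moves`` Metropolis moves in place; returns total dE."""
    np.random.seed(seed)
    n_beads = pos.shape[0]
    n_chains = chain_starts.shape[0]
    de_total = 0.0
    # scratch buffers for cluster moves
    in_cluster = np.zeros(n_chains, dtype=np.uint8)
    stack = np.empty(n_chains, dtype=np.int64)

    for _ in range(n_moves):
        u = np.random.random()
        kind = 0
        while cum_probs[kind] < u:
            kind += 1
        attempts[kind] += 1

        if kind == 0:
            # ---- local single-bead move
            b = np.random.randint(n_beads)
            o = np.random.randint(26)
            x, y, z = pos[b, 0], pos[b, 1], pos[b, 2]
            nx = (x + offsets[o, 0]) % box
            ny = (y + offsets[o, 1]) % box
            nz = (z + offsets[o, 2]) % box
            if occ[nx, ny, nz] != 0:
                continue
            c = chain_of[b]
            s = chain_starts[c]
            L = chain_lens[c]
            ok = True
            if b > s:
                if _cheb_dist(nx, ny, nz, pos[b - 1, 0], pos[b - 1, 1],
                              pos[b - 1, 2], box) > 1:
                    ok = False
            if ok and b < s + L - 1:
                if _cheb_dist(nx, ny, nz, pos[b + 1, 0], pos[b + 1, 1],
                              pos[b + 1, 2], box) > 1:
                    ok = False
            if not ok:
                continue
            occ[x, y, z] = 0
            e0 = _env_energy(b, x, y, z, occ, types, chain_of, energies, box, offsets)
            e1 = _env_energy(b, nx, ny, nz, occ, types, chain_of, energies, box, offsets)
            de = e1 - e0
            if de <= 0.0 or np.random.random() < math.exp(-de / T):
                pos[b, 0], pos[b, 1], pos[b, 2] = nx, ny, nz
                occ[nx, ny, nz] = b + 1
                de_total += de
                accepts[kind] += 1
            else:
                occ[x, y, z] = b + 1

        elif kind == 1:
            # ---- co-local move of a bonded pair
            b = np.random.randint(n_beads)
            c = chain_of[b]
            s = chain_starts[c]
            L = chain_lens[c]
            if L < 2:
                continue
            if b == s + L - 1:
                b -= 1
            b2 = b + 1
            o = np.random.randint(26)
            ox, oy, oz = offsets[o, 0], offsets[o, 1], offsets[o, 2]
            ax, ay, az = pos[b, 0], pos[b, 1], pos[b, 2]
            bx, by, bz = pos[b2, 0], pos[b2, 1], pos[b2, 2]
            nax, nay, naz = (ax + ox) % box, (ay + oy) % box, (az + oz) % box
            nbx, nby, nbz = (bx + ox) % box, (by + oy) % box, (bz + oz) % box
            occ[ax, ay, az] = 0
            occ[bx, by, bz] = 0
            ok = occ[nax, nay, naz] == 0 and occ[nbx, nby, nbz] == 0
            if ok and b > s:
                if _cheb_dist(nax, nay, naz, pos[b - 1, 0], pos[b - 1, 1],
                              pos[b - 1, 2], box) > 1:
                    ok = False
            if ok and b2 < s + L - 1:
                if _cheb_dist(nbx, nby, nbz, pos[b2 + 1, 0], pos[b2 + 1, 1],
                              pos[b2 + 1, 2], box) > 1:
                    ok = False
            if not ok:
                occ[ax, ay, az] = b + 1
                occ[bx, by, bz] = b2 + 1
                continue
            e0 = (_env_energy(b, ax, ay, az, occ, types, chain_of, energies, box, offsets)
                  + _env_energy(b2, bx, by, bz, occ, types, chain_of, energies, box, offsets))
            e1 = (_env_energy(b, nax, nay, naz, occ, types, chain_of, energies, box, offsets)
                  + _env_energy(b2, nbx, nby, nbz, occ, types, chain_of, energies, box, offsets))
            de = e1 - e0
            if de <= 0.0 or np.random.random() < math.exp(-de / T):
                pos[b, 0], pos[b, 1], pos[b, 2] = nax, nay, naz
                pos[b2, 0], pos[b2, 1], pos[b2, 2] = nbx, nby, nbz
                occ[nax, nay, naz] = b + 1
                occ[nbx, nby, nbz] = b2 + 1
                de_total += de
                accepts[kind] += 1
            else:
                occ[ax, ay, az] = b + 1
                occ[bx, by, bz] = b2 + 1

        elif kind == 2:
            # ---- reptation (slithering snake)
            c = np.random.randint(n_chains)
            s = chain_starts[c]
            L = chain_lens[c]
            if L < 2:
                continue
            headward = np.random.random() < 0.5
            o = np.random.randint(26)
            if headward:
                hx, hy, hz = pos[s + L - 1, 0], pos[s + L - 1, 1], pos[s + L - 1, 2]
                tx, ty, tz = pos[s, 0], pos[s, 1], pos[s, 2]
            else:
                hx, hy, hz = pos[s, 0], pos[s, 1], pos[s, 2]
                tx, ty, tz = pos[s + L - 1, 0], pos[s + L - 1, 1], pos[s + L - 1, 2]
            nx = (hx + offsets[o, 0]) % box
            ny = (hy + offsets[o, 1]) % box
            nz = (hz + offsets[o, 2]) % box
            occ_val = occ[nx, ny, nz]
            if occ_val != 0 and not (nx == tx and ny == ty and nz == tz):
                continue
            if nx == hx and ny == hy and nz == hz:
                continue
            e_before = _chain_energy(c, pos, occ, types, chain_of, chain_starts,
                                     chain_lens, energies, box, offsets)
            old_pos = pos[s:s + L].copy()
            # vacate the chain, shift coordinates, occupy new sites
            for i in range(s, s + L):
                occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
            if headward:
                for i in range(s, s + L - 1):
                    pos[i, 0] = old_pos[i - s + 1, 0]
                    pos[i, 1] = old_pos[i - s + 1, 1]
                    pos[i, 2] = old_pos[i - s + 1, 2]
                pos[s + L - 1, 0], pos[s + L - 1, 1], pos[s + L - 1, 2] = nx, ny, nz
            else:
                for i in range(s + 1, s + L):
                    pos[i, 0] = old_pos[i - s - 1, 0]
                    pos[i, 1] = old_pos[i - s - 1, 1]
                    pos[i, 2] = old_pos[i - s - 1, 2]
                pos[s, 0], pos[s, 1], pos[s, 2] = nx, ny, nz
            for i in range(s, s + L):
                occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1
            e_after = _chain_energy(c, pos, occ, types, chain_of, chain_starts,
                                    chain_lens, energies, box, offsets)
            de = e_after - e_before
            if de <= 0.0 or np.random.random() < math.exp(-de / T):
                de_total += de
                accepts[kind] += 1
            else:
                for i in range(s, s + L):
                    occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
                for i in range(s, s + L):
                    pos[i, 0] = old_pos[i - s, 0]
                    pos[i, 1] = old_pos[i - s, 1]
                    pos[i, 2] = old_pos[i - s, 2]
                for i in range(s, s + L):
                    occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1

        elif kind == 3:
            # ---- whole-chain translation by a unit offset
            c = np.random.randint(n_chains)
            s = chain_starts[c]
            L = chain_lens[c]
            o = np.random.randint(26)
            ox, oy, oz = offsets[o, 0], offsets[o, 1], offsets[o, 2]
            for i in range(s, s + L):
                occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
            ok = True
            for i in range(s, s + L):
                nx = (pos[i, 0] + ox) % box
                ny = (pos[i, 1] + oy) % box
                nz = (pos[i, 2] + oz) % box
                if occ[nx, ny, nz] != 0:
                    ok = False
                    break
            if not ok:
                for i in range(s, s + L):
                    occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1
                continue
            e0 = 0.0
            e1 = 0.0
            for i in range(s, s + L):
                e0 += _env_energy(i, pos[i, 0], pos[i, 1], pos[i, 2], occ,
                                  types, chain_of, energies, box, offsets)
                e1 += _env_energy(i, (pos[i, 0] + ox) % box, (pos[i, 1] + oy) % box,
                                  (pos[i, 2] + oz) % box, occ,
                                  types, chain_of, energies, box, offsets)
            de = e1 - e0
            if de <= 0.0 or np.random.random() < math.exp(-de / T):
                for i in range(s, s + L):
                    pos[i, 0] = (pos[i, 0] + ox) % box
                    pos[i, 1] = (pos[i, 1] + oy) % box
                    pos[i, 2] = (pos[i, 2] + oz) % box
                    occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1
                de_total += de
                accepts[kind] += 1
            else:
                for i in range(s, s + L):
                    occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1

        else:
            # ---- cluster translation with no-merge rule (dE = 0)
            c0 = np.random.randint(n_chains)
            for i in range(n_chains):
                in_cluster[i] = 0
            in_cluster[c0] = 1
            n_in = 1
            max_cluster = n_chains // 2  # translating a system-spanning
            stack[0] = c0                # cluster relaxes nothing
            top = 1
            aborted = False
            while top > 0:
                top -= 1
                c = stack[top]
                s = chain_starts[c]
                for i in range(s, s + chain_lens[c]):
                    x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
                    for k in range(26):
                        j = occ[(x + offsets[k, 0]) % box,
                                (y + offsets[k, 1]) % box,
                                (z + offsets[k, 2]) % box] - 1
                        if j >= 0:
                            cj = chain_of[j]
                            if in_cluster[cj] == 0:
                                in_cluster[cj] = 1
                                stack[top] = cj
                                top += 1
                                n_in += 1
                if n_in > max_cluster:
                    aborted = True
                    break
            if aborted:
                continue
            o = np.random.randint(26)
            ox, oy, oz = offsets[o, 0], offsets[o, 1], offsets[o, 2]
            # vacate the cluster
            for c in range(n_chains):
                if in_cluster[c] == 1:
                    s = chain_starts[c]
                    for i in range(s, s + chain_lens[c]):
                        occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
            # reject on overlap or any new contact with outside beads
            ok = True
            for c in range(n_chains):
                if not ok:
                    break
                if in_cluster[c] == 1:
                    s = chain_starts[c]
                    for i in range(s, s + chain_lens[c]):
                        nx = (pos[i, 0] + ox) % box
                        ny = (pos[i, 1] + oy) % box
                        nz = (pos[i, 2] + oz) % box
                        if occ[nx, ny, nz] != 0:
                            ok = False
                            break
                        for k in range(26):
                            if occ[(nx + offsets[k, 0]) % box,
                                   (ny + offsets[k, 1]) % box,
                                   (nz + offsets[k, 2]) % box] != 0:
                                ok = False
                                break
                        if not ok:
                            break
            if ok:
                for c in range(n_chains):
                    if in_cluster[c] == 1:
                        s = chain_starts[c]
                        for i in range(s, s + chain_lens[c]):
                            pos[i, 0] = (pos[i, 0] + ox) % box
                            pos[i, 1] = (pos[i, 1] + oy) % box
                            pos[i, 2] = (pos[i, 2] + oz) % box
                accepts[kind] += 1
            for c in range(n_chains):
                if in_cluster[c] == 1:
                    s = chain_starts[c]
                    for i in range(s, s + chain_lens[c]):
                        occ[pos[i, 0], pos[i, 1], pos[i, 2]] = i + 1

    return de_total


# ---------------------------------------------------------------------------
# Public energy / sweep API
# ---------------------------------------------------------------------------

def total_energy(config: LatticeConfiguration, model: ContactModel) -> float:
    """Total contact energy: sum of eps(a, b) over unordered nonbonded
    bead pairs within the 26-site neighborhood (minimum image)."""
    return float(
        _total_energy_kernel(
            config.positions,
            config.occupancy(),
            config.types,
            config.chain_of,
            model.energies,
            config.box_side,
            OFFSETS26,
            N_HALF,
        )
    )


@dataclass
class Frame:
    step: int
    positions: np.ndarray
    energy: float


@dataclass
class Trajectory:
    """Snapshots of an MC run (chains and topology are fixed)."""

    box_side: int
    chain_lens: np.ndarray
    sequences: list[EncodedSequence]
    chain_seq_index: np.ndarray
    T: float
    seed: int
    frames: list[Frame] = field(default_factory=list)
    move_attempts: np.ndarray = field(
        default_factory=lambda: np.zeros(len(MOVE_NAMES), dtype=np.int64)
    )
    move_accepts: np.ndarray = field(
        default_factory=lambda: np.zeros(len(MOVE_NAMES), dtype=np.int64)
    )
    equilibrated_from: int = 0
    local_only: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_chains(self) -> int:
        return len(self.chain_lens)

    def configuration(self, i: int) -> LatticeConfiguration:
        return LatticeConfiguration(
            self.box_side,
            self.frames[i].positions,
            self.chain_lens,
            self.sequences,
            self.chain_seq_index,
        )

    def equilibrated(self) -> list[int]:
        """Frame indices in the equilibrated portion."""
        return list(range(self.equilibrated_from, self.n_frames))

    def acceptance_rate(self) -> float:
        a = self.move_attempts.sum()
        return float(self.move_accepts.sum() / a) if a else float("nan")


def metropolis_sweep(
    config: LatticeConfiguration,
    model: ContactModel,
    T: float,
    moves: MoveSet,
    seed: int,
    n_moves: int | None = None,
    occ: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Attempt ``n_moves`` (default one per bead) Metropolis moves
    in place on ``config``.  Returns (dE, attempts, accepts)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if occ is None:
        occ = config.occupancy()
    attempts = np.zeros(len(MOVE_NAMES), dtype=np.int64)
    accepts = np.zeros(len(MOVE_NAMES), dtype=np.int64)
    de = _run_mc(
        config.positions, occ, config.types, config.chain_of,
        config.chain_starts, config.chain_lens, config.sticker_mask,
        model.energies, config.box_side, float(T),
        int(n_moves if n_moves is not None else config.n_beads),
        moves.cumulative, int(seed) & 0x7FFFFFFF, OFFSETS26,
        attempts, accepts,
    )
    return float(de), attempts, accepts


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

def _place_chains(
    box: int,
    chain_lens: np.ndarray,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
    max_restarts: int = 20000,
) -> np.ndarray:
    """Grow chains as random walks on vacant (optionally ``allowed``)
    sites; restarts a chain on dead ends."""
    occ = np.zeros((box, box, box), dtype=bool)
    if allowed is not None:
        n_avail = int(allowed.sum())
    else:
        n_avail = box**3
    if chain_lens.sum() > n_avail:
        raise ValueError("infeasible packing: more beads than available sites")
    out = np.empty((int(chain_lens.sum()), 3), dtype=np.int64)
    pos_i = 0
    for L in chain_lens:
        placed = None
        for _ in range(max_restarts):
            trial = _grow_one(box, int(L), occ, allowed, rng)
            if trial is not None:
                placed = trial
                break
        if placed is None:
            raise ValueError("could not place chains (packing too dense)")
        for p in placed:
            occ[p[0], p[1], p[2]] = True
        out[pos_i:pos_i + L] = placed
        pos_i += L
    return out


def _grow_one(box, L, occ, allowed, rng):
    if allowed is not None:
        starts = np.argwhere(allowed & ~occ)
    else:
        starts = np.argwhere(~occ)
    if len(starts) == 0:
        return None
    cur = starts[rng.integers(len(starts))]
    chain = [cur]
    taken = {tuple(cur)}
    for _ in range(L - 1):
        order = rng.permutation(26)
        nxt = None
        for k in order:
            cand = (cur + OFFSETS26[k]) % box
            t = tuple(cand)
            if t in taken:
                continue
            if occ[t]:
                continue
            if allowed is not None and not allowed[t]:
                continue
            nxt = cand
            break
        if nxt is None:
            return None
        chain.append(nxt)
        taken.add(tuple(nxt))
        cur = nxt
    return np.array(chain, dtype=np.int64)


def initial_configuration(
    sequences: list[EncodedSequence],
    counts: list[int],
    box_side: int,
    seed: int,
    start: str = "random",
    droplet_packing: float = 0.55,
) -> LatticeConfiguration:
    """Build a legal starting configuration.

    ``start="random"`` scatters chains through the box; ``"droplet"``
    grows them inside a central ball sized for ``droplet_packing``
    occupancy (a pre-formed droplet for condensate studies).
    """
    rng = np.random.default_rng(seed)
    chain_lens = []
    chain_seq_index = []
    for si, (seq, cnt) in enumerate(zip(sequences, counts)):
        for _ in range(cnt):
            chain_lens.append(len(seq))
            chain_seq_index.append(si)
    chain_lens = np.array(chain_lens, dtype=np.int64)
    n_beads = int(chain_lens.sum())
    if n_beads >= box_side**3:
        raise ValueError("infeasible packing: total beads >= box volume")
    allowed = None
    if start == "droplet":
        r = (3 * n_beads / (4 * math.pi * droplet_packing)) ** (1 / 3)
        if 2 * r >= box_side:
            raise ValueError("droplet does not fit in the box")
        g = np.arange(box_side)
        cx = box_side / 2 - 0.5
        d2 = ((g - cx) ** 2)[:, None, None] + ((g - cx) ** 2)[None, :, None] \
            + ((g - cx) ** 2)[None, None, :]
        allowed = d2 <= r * r
    elif start != "random":
        raise ValueError(f"unknown start mode {start!r}")
    positions = _place_chains(box_side, chain_lens, rng, allowed)
    cfg = LatticeConfiguration(
        box_side, positions, chain_lens,
        list(sequences), np.array(chain_seq_index, dtype=np.int64),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def run_simulation(
    sequences: list[EncodedSequence] | EncodedSequence,
    counts: list[int] | int,
    model: ContactModel,
    T: float,
    box_side: int,
    n_sweeps: int,
    moves: MoveSet | None = None,
    seed: int = 0,
    snapshot_interval: int = 100,
    start: str = "random",
    initial: LatticeConfiguration | None = None,
    equilibration_fraction: float = 0.5,
) -> Trajectory:
    """Run Metropolis MC and return a thinned trajectory.

    One sweep attempts ``n_beads`` moves.  The first
    ``equilibration_fraction`` of stored frames is marked as the
    equilibration window (``Trajectory.equilibrated_from``); analyses
    use the remaining frames.  Bit-reproducible for a fixed seed.
    """
    if isinstance(sequences, EncodedSequence):
        sequences = [sequences]
    if isinstance(counts, int):
        counts = [counts]
    if moves is None:
        moves = MoveSet()
    if initial is not None:
        cfg = initial.copy()
    else:
        cfg = initial_configuration(sequences, counts, box_side, seed, start=start)
    occ = cfg.occupancy()
    energy = total_energy(cfg, model)
    traj = Trajectory(
        box_side=cfg.box_side,
        chain_lens=cfg.chain_lens,
        sequences=cfg.sequences,
        chain_seq_index=cfg.chain_seq_index,
        T=float(T),
        seed=int(seed),
        local_only=moves.local_only,
    )
    traj.frames.append(Frame(0, cfg.positions.copy(), energy))
    n_moves_per_sweep = cfg.n_beads
    rng = np.random.default_rng(seed)
    done = 0
    while done < n_sweeps:
        chunk = min(snapshot_interval, n_sweeps - done)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        de, att, acc = metropolis_sweep(
            cfg, model, T, moves, sub_seed,
            n_moves=chunk * n_moves_per_sweep, occ=occ,
        )
        energy += de
        done += chunk
        traj.move_attempts += att
        traj.move_accepts += acc
        traj.frames.append(Frame(done * n_moves_per_sweep, cfg.positions.copy(), energy))
    traj.equilibrated_from = max(1, int(len(traj.frames) * equilibration_fraction))
    return traj


def energy_stationarity(traj: Trajectory) -> tuple[float, float]:
    """Split-half stationarity check on the equilibrated energies.

    Returns (|mean difference|, 2 * pooled SE); the run is considered
    stationary when the first value is below the second.
    """
    e = np.array([f.energy for f in traj.frames[traj.equilibrated_from:]])
    if len(e) < 4:
        return float("nan"), float("nan")
    a, b = e[: len(e) // 2], e[len(e) // 2:]
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    return abs(float(a.mean() - b.mean())), 2 * se


# ---------------------------------------------------------------------------
# Single-chain scaling and chain dynamics
# ---------------------------------------------------------------------------

def internal_distances(
    traj: Trajectory,
    frames: list[int] | None = None,
    end_margin: float = 0.0,
):
    """Mean-square internal distance <R^2(s)> vs sequence separation s,
    averaged over the (equilibrated) frames of a single-chain run.

    ``end_margin`` (fraction of the chain) excludes pairs with either
    residue inside the chain-end regions, which are systematically less
    swollen and depress the apparent scaling exponent.
    """
    if traj.n_chains != 1:
        raise ValueError("internal_distances expects a single-chain trajectory")
    if frames is None:
        frames = traj.equilibrated()
    L = int(traj.chain_lens[0])
    lo, hi = int(L * end_margin), int(L * (1 - end_margin))
    acc = np.zeros(L)
    cnt = np.zeros(L)
    for fi in frames:
        u = traj.configuration(fi).unwrapped_chain(0)
        for s in range(1, L):
            i0 = np.arange(0, L - s)
            keep = (i0 >= lo) & (i0 + s <= hi)
            if not keep.any():
                continue
            d = u[i0[keep] + s] - u[i0[keep]]
            acc[s] += (d**2).sum(axis=1).mean()
            cnt[s] += 1
    s_vals = np.arange(1, L)
    with np.errstate(invalid="ignore"):
        r2 = acc[1:] / cnt[1:]
    return s_vals[cnt[1:] > 0], r2[cnt[1:] > 0]


def single_chain_nu(
    traj: Trajectory,
    s_min: int = 2,
    s_max: int | None = None,
    end_margin: float = 0.2,
    min_frames: int = 10,
) -> tuple[float, float]:
    """Apparent Flory scaling exponent nu from internal distances.

    Fits log <R^2(s)>^(1/2) against log s over the window
    [s_min, s_max] (default s_max = N/3), restricted to interior pairs
    (``end_margin`` on both chain ends).  Returns (nu, stderr of the
    regression slope).
    """
    frames = traj.equilibrated()
    if len(frames) < min_frames:
        raise ValueError(f"need >= {min_frames} equilibrated frames")
    L = int(traj.chain_lens[0])
    if s_max is None:
        s_max = L // 3
    s, r2 = internal_distances(traj, frames, end_margin=end_margin)
    sel = (s >= s_min) & (s <= s_max)
    if sel.sum() < 3:
        raise ValueError("scaling window too narrow")
    x = np.log(s[sel].astype(float))
    y = 0.5 * np.log(r2[sel])
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = len(x)
    resid = y - A @ coef
    s2 = float(resid @ resid) / max(n - 2, 1)
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[0]), float(math.sqrt(cov[0, 0]))


def chain_coms(traj: Trajectory, frames: list[int] | None = None) -> np.ndarray:
    """Unwrapped chain center-of-mass tracks, shape (n_frames, n_chains, 3).

    Per-frame COMs are stitched together with minimum-image
    displacements so diffusion over many box lengths is preserved.
    """
    if frames is None:
        frames = list(range(traj.n_frames))
    box = traj.box_side
    rows = []
    for fi in frames:
        cfg = traj.configuration(fi)
        rows.append([cfg.chain_com(c) for c in range(traj.n_chains)])
    coms_raw = np.array(rows)
    out = np.empty_like(coms_raw)
    out[0] = coms_raw[0]
    for i in range(1, len(frames)):
        d = coms_raw[i] - coms_raw[i - 1]
        d -= box * np.round(d / box)
        out[i] = out[i - 1] + d
    return out


def chain_rmsd_over_steps(traj: Trajectory, step_lag: int) -> np.ndarray:
    """Per-chain center-of-mass RMSD over a lag of ``step_lag`` MC moves.

    Requires a local-only trajectory (global translations would corrupt
    the MC-step proxy for time).
    """
    if not traj.local_only:
        raise ValueError("chain RMSD requires a local-only move set")
    steps = np.array([f.step for f in traj.frames])
    d_steps = np.diff(steps)
    if not len(d_steps):
        raise ValueError("trajectory too short")
    per = int(round(step_lag / d_steps[0]))
    if per < 1 or per >= traj.n_frames:
        raise ValueError("lag outside trajectory span")
    coms = chain_coms(traj)
    disp = coms[per:] - coms[:-per]
    return np.sqrt((disp**2).sum(axis=2).mean(axis=0))
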
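"""Sequence encoding and the contact-energy model.

Prion-like low-complexity domains (PLCDs) are modelled one bead per
residue over a reduced ten-letter alphabet: nine named residue types
(Y, F, R, K, G, S, T, Q, N) plus a generic residue X that absorbs every
other standard amino acid.  Tyrosine and phenylalanine are the primary
stickers; arginine acts as an auxiliary sticker through its contact
energies only and is never flagged in the sticker mask.

The interaction model is a symmetric 10x10 table of pairwise contact
energies in dimensionless simulation units (kB = 1).  Two beads are in
contact when they occupy lattice sites within sqrt(3) lattice units,
i.e. the 26-site neighborhood on the cubic lattice.  A mean-field net
charge per residue (NCPR) adjustment can weaken or strengthen the
attractive entries in proportion to the NCPR difference between a
variant and the reference sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: The reduced model alphabet, in table order.
ALPHABET: tuple[str, ...] = ("Y", "F", "R", "K", "G", "S", "T", "Q", "N", "X")
ALPHABET_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: Residues carrying the sticker flag (aromatic crosslinkers).
STICKER_RESIDUES = frozenset({"Y", "F"})

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
# 'X' (the reduced generic type) is accepted on input so that encoding
# an already-reduced string is a no-op; it carries no charge.
_ACCEPTED = STANDARD_AA | {"X"}

#: Formal charges at neutral pH used for NCPR (His and Cys neutral).
_CHARGE = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0}

CONTACT_RANGE = math.sqrt(3.0)


@dataclass(frozen=True)
class EncodedSequence:
    """A residue string reduced to the ten-type model alphabet.

    ``residues`` holds the reduced one-letter codes; ``codes`` the same
    as integer indices into :data:`ALPHABET` (handy for kernels);
    ``sticker_mask`` is True exactly at Y/F positions; ``ncpr`` is the
    net charge per residue of the *original* sequence.
    """

    id: str
    residues: tuple[str, ...]
    raw_residues: str
    sticker_mask: np.ndarray
    ncpr: float

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if not -1.0 <= self.ncpr <= 1.0:
            raise ValueError(f"ncpr {self.ncpr} outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return np.array([ALPHABET_INDEX[r] for r in self.residues], dtype=np.int8)

    @property
    def n_stickers(self) -> int:
        return int(self.sticker_mask.sum())

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.residues:
            out[r] = out.get(r, 0) + 1
        return out


def encode_sequence(raw: str, id: str = "seq") -> EncodedSequence:
    """Encode a 20-letter amino-acid string into the model alphabet.

    Y, F, R, K, G, S, T, Q, N are preserved; every other standard
    residue maps to the generic type X.  NCPR is computed from the raw
    sequence (R, K -> +1; D, E -> -1; H neutral) divided by length.

    Raises
    ------
    ValueError
        If ``raw`` is empty or contains a character outside the 20
        standard one-letter codes (the offending position is named).
    """
    raw = raw.strip().upper()
    if not raw:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(raw):
        if ch not in _ACCEPTED:
            raise ValueError(
                f"unknown residue {ch!r} at position {pos} in sequence {id!r}"
            )
    residues = tuple(ch if ch in ALPHABET_INDEX else "X" for ch in raw)
    mask = np.array([r in STICKER_RESIDUES for r in residues], dtype=bool)
    ncpr = sum(_CHARGE.get(ch, 0.0) for ch in raw) / len(raw)
    return EncodedSequence(
        id=id, residues=residues, raw_residues=raw, sticker_mask=mask, ncpr=ncpr
    )


@dataclass(frozen=True)
class ContactModel:
    """Symmetric pairwise contact energies over the model alphabet.

    Parameters
    ----------
    energies
        (10, 10) symmetric array, simulation energy units; negative
        entries are attractions.
    contact_range
        Contact distance on the lattice, default sqrt(3) (the 26-site
        neighborhood).
    ncpr_coefficient
        Proportionality constant kappa of the mean-field NCPR
        adjustment; 0 disables it.
    reference_ncpr
        NCPR of the reference (wild-type) sequence the adjustment is
        measured against.
    """

    energies: np.ndarray
    contact_range: float = CONTACT_RANGE
    ncpr_coefficient: float = 0.0
    reference_ncpr: float = 0.0
    kB: float = field(default=1.0, init=False)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"energy table must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.allclose(e, e.T, atol=1e-9):
            raise ValueError("energy table is not symmetric")
        if self.contact_range <= 0:
            raise ValueError("contact_range must be positive")
        if not math.isfinite(self.ncpr_coefficient):
            raise ValueError("ncpr_coefficient must be finite")
        object.__setattr__(self, "energies", 0.5 * (e + e.T))

    def energy(self, a: str, b: str) -> float:
        return float(self.energies[ALPHABET_INDEX[a], ALPHABET_INDEX[b]])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.energies, index=ALPHABET, columns=ALPHABET)


@dataclass(frozen=True)
class AdjustedModel:
    """A ContactModel after the mean-field NCPR adjustment."""

    base: ContactModel
    delta_ncpr: float
    effective: ContactModel


def adjust_model_for_ncpr(model: ContactModel, seq: EncodedSequence) -> AdjustedModel:
    """Apply the mean-field NCPR adjustment for ``seq``.

    Attractive entries (negative energies) are weakened additively by
    ``kappa * |NCPR(seq) - reference_ncpr|``; repulsive/neutral entries
    are untouched.  With ``kappa = 0`` or a zero NCPR difference the
    effective model equals the base model bit-identically.
    """
    delta = seq.ncpr - model.reference_ncpr
    shift = model.ncpr_coefficient * abs(delta)
    if shift == 0.0:
        return AdjustedModel(base=model, delta_ncpr=delta, effective=model)
    e = model.energies.copy()
    attractive = e < 0
    e[attractive] = e[attractive] + shift
    eff = replace(model, energies=e)
    return AdjustedModel(base=model, delta_ncpr=delta, effective=eff)


def make_homopolymer_equivalent(
    length: int,
    epsilon: float,
    template: EncodedSequence | None = None,
) -> tuple[EncodedSequence, ContactModel]:
    """Build the homopolymer-equivalent sequence and uniform model.

    Every pairwise energy equals ``epsilon`` (a value of -3.3 makes the
    homopolymer phase diagram overlay the wild-type one at full scale).
    If ``template`` is given, its sticker mask is imposed on the
    homopolymer so ratio-of-association analyses can reference it;
    residue identities stay uniform (all X), so energies are unchanged.
    """
    if length < 2:
        raise ValueError("homopolymer length must be >= 2")
    residues = tuple("X" for _ in range(length))
    if template is not None:
        if len(template) != length:
            raise ValueError("template length does not match requested length")
        mask = template.sticker_mask.copy()
    else:
        mask = np.zeros(length, dtype=bool)
    seq = EncodedSequence(
        id=f"homopolymer_{length}",
        residues=residues,
        raw_residues="G" * length,
        sticker_mask=mask,
        ncpr=0.0,
    )
    n = len(ALPHABET)
    model = ContactModel(energies=np.full((n, n), float(epsilon)))
    return seq, model


_VARIANT_TOKEN = re.compile(r"([+-])(\d+)([A-Z])")


def apply_variant(
    seq: EncodedSequence, descriptor: str, spacer: str = "G"
) -> EncodedSequence:
    """Apply a variant descriptor such as ``-12F+12Y`` or ``-4F-2Y``.

    The mini-grammar pairs removals with additions of equal count into
    substitutions (``-12F+12Y`` turns 12 F into Y).  Unpaired removals
    replace the named residue with ``spacer`` (an aromatic deletion
    becomes a spacer); unpaired additions are rejected since there is no
    position to place them.  When fewer than all occurrences are
    replaced, evenly spaced occurrences are chosen so the roughly
    uniform patterning of aromatics along PLCDs is preserved.
    """
    descriptor = descriptor.strip()
    if not descriptor:
        return seq
    tokens = _VARIANT_TOKEN.findall(descriptor)
    if "".join(f"{s}{n}{r}" for s, n, r in tokens) != descriptor.replace(" ", ""):
        raise ValueError(f"cannot parse variant descriptor {descriptor!r}")
    raw = list(seq.raw_residues)

    def substitute(old: str, new: str, count: int):
        positions = [i for i, ch in enumerate(raw) if ch == old]
        if count > len(positions):
            raise ValueError(
                f"descriptor asks for {count} x {old} but only "
                f"{len(positions)} present"
            )
        # evenly spaced selection among the occurrences
        if count == len(positions):
            chosen = positions
        else:
            idx = np.linspace(0, len(positions) - 1, count)
            chosen = [positions[int(round(i))] for i in idx]
        for p in chosen:
            raw[p] = new

    i = 0
    while i < len(tokens):
        sign, n_str, res = tokens[i]
        n = int(n_str)
        if (
            sign == "-"
            and i + 1 < len(tokens)
            and tokens[i + 1][0] == "+"
            and int(tokens[i + 1][1]) == n
        ):
            substitute(res, tokens[i + 1][2], n)
            i += 2
        elif sign == "-":
            substitute(res, spacer, n)
            i += 1
        else:
            raise ValueError(
                f"unpaired addition {sign}{n}{res} in {descriptor!r}: "
                "additions must pair with a removal of equal count"
            )
    new_id = f"{seq.id}{descriptor}"
    return encode_sequence("".join(raw), id=new_id)


# ---------------------------------------------------------------------------
# File I/O: FASTA sequences and TSV energy tables
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path) -> list[EncodedSequence]:
    """Read a FASTA file into encoded sequences (file order preserved)."""
    seqs: list[EncodedSequence] = []
    label: str | None = None
    chunks: list[str] = []

    def flush():
        if label is not None:
            seqs.append(encode_sequence("".join(chunks), id=label))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                label = line[1:].split()[0] if len(line) > 1 else "seq"
                chunks = []
            else:
                if label is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_sequences(path: str | Path, seqs: list[EncodedSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.raw_residues}\n")


def read_energy_table(
    path: str | Path,
    *,
    symmetry_tol: float = 1e-9,
    **model_kwargs,
) -> ContactModel:
    """Read a labelled 10x10 TSV energy matrix into a ContactModel.

    The header row/column must name all ten residue types (any order).
    An asymmetry beyond ``symmetry_tol`` or a missing residue type is
    rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", index_col=0, comment="#")
    rows = [str(r).upper() for r in df.index]
    cols = [str(c).upper() for c in df.columns]
    missing = set(ALPHABET) - set(rows) or set(ALPHABET) - set(cols)
    if missing:
        raise ValueError(f"{path}: energy table missing residue types {sorted(missing)}")
    df.index, df.columns = rows, cols
    df = df.loc[list(ALPHABET), list(ALPHABET)]
    e = df.to_numpy(dtype=float)
    asym = np.abs(e - e.T).max()
    if asym > symmetry_tol:
        raise ValueError(f"{path}: energy table asymmetric (max |e-eT| = {asym:.3g})")
    return ContactModel(energies=0.5 * (e + e.T), **model_kwargs)


def write_energy_table(path: str | Path, model: ContactModel) -> None:
    model.as_frame().to_csv(path, sep="\t", float_format="%.6g")


def default_contact_model(**model_kwargs) -> ContactModel:
    """Load the packaged default contact-energy table.

    The packaged table is a synthetic stand-in (see its header comment)
    that honours the published qualitative constraints: the sticker
    hierarchy |e_YY| > |e_YF| > |e_FF| > |e_R-aromatic| and a Y-Y to
    Y-K swap magnitude of ~0.47 kBT at T=40 and ~0.32 kBT at T=60.
    """
    ref = resources.files("sticklat.data") / "contact_energies_synthetic_default.tsv"
    with resources.as_file(ref) as p:
        return read_energy_table(p, **model_kwargs)
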
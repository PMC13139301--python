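"""Protein representations for the two protein heads of the model.

Local head input: label encoding of the amino-acid sequence (A=1 ... Y=20
in alphabetical one-letter order, UNKNOWN=21, 0 = padding), truncated or
zero-padded to exactly 1,000 positions.

Global head input: a sequence-derived descriptor vector.  The built-in
provider emits, in fixed order, amino-acid composition (20), overlapping
dipeptide composition (400) and CTD composition/transition/distribution
(147), width 567.  Wider externally computed matrices (e.g. the full
autocorrelation/QSO/PseAAC families) can be plugged in through the same
provider contract.
"""

from __future__ import annotations

import logging

import numpy as np

from .data_io import AMINO_ACIDS

logger = logging.getLogger(__name__)

PROTEIN_ENCODING_LENGTH = 1000
UNKNOWN_INDEX = 21

_AA_INDEX = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
_AA_POS = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_sequence(sequence: str, length: int = PROTEIN_ENCODING_LENGTH) -> np.ndarray:
    """Label-encode a sequence to a fixed-length integer vector.

    Residues outside the 20 standard one-letter codes map to UNKNOWN (21);
    sequences longer than ``length`` keep their first ``length`` residues.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    out = np.zeros(length, dtype=np.int64)
    for pos, aa in enumerate(sequence[:length].upper()):
        out[pos] = _AA_INDEX.get(aa, UNKNOWN_INDEX)
    return out


# --------------------------------------------------------------------------
# CTD attribute groupings (three classes per attribute).
# Standard tables dividing the 20 amino acids into three classes for seven
# physicochemical attributes, as used throughout the CTD descriptor
# literature and the common protein-descriptor toolkits.
# --------------------------------------------------------------------------
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

# each attribute: every amino acid in exactly one of the three classes
for _attr, _groups in CTD_GROUPS.items():
    assert sorted("".join(_groups)) == sorted(AMINO_ACIDS), _attr


class ProteinDescriptorError(Exception):
    pass


def _clean(sequence: str) -> str:
    """Uppercase and drop non-standard residues (with a warning)."""
    seq = sequence.upper()
    kept = "".join(aa for aa in seq if aa in _AA_POS)
    if len(kept) < len(seq):
        logger.warning(
            "skipped %d non-standard residues in descriptor computation",
            len(seq) - len(kept),
        )
    return kept


def amino_acid_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 20 amino acids; sums to 1."""
    counts = np.zeros(20)
    for aa in sequence:
        counts[_AA_POS[aa]] += 1
    return counts / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Overlapping dipeptide frequencies, 400 entries in AA x AA order; sums to 1."""
    counts = np.zeros(400)
    for a, b in zip(sequence, sequence[1:]):
        counts[_AA_POS[a] * 20 + _AA_POS[b]] += 1
    return counts / (len(sequence) - 1)


def _ctd_single(sequence: str, groups: tuple[str, str, str]) -> np.ndarray:
    """C (3) + T (3) + D (15) descriptors for one attribute grouping.

    Composition: fraction of residues per class.  Transition: fraction of
    adjacent pairs crossing each unordered class pair (1-2, 1-3, 2-3).
    Distribution: for each class, the fractional sequence position of its
    first occurrence and of the occurrences at the 25/50/75/100% quantiles
    of its residue count (ceil convention); zeros when the class is absent.
    """
    n = len(sequence)
    cls = np.empty(n, dtype=np.int64)
    lookup = {}
    for g, members in enumerate(groups):
        for aa in members:
            lookup[aa] = g
    for i, aa in enumerate(sequence):
        cls[i] = lookup[aa]

    comp = np.bincount(cls, minlength=3) / n

    trans = np.zeros(3)
    if n > 1:
        a, b = cls[:-1], cls[1:]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        trans[0] = np.sum((lo == 0) & (hi == 1))
        trans[1] = np.sum((lo == 0) & (hi == 2))
        trans[2] = np.sum((lo == 1) & (hi == 2))
        trans /= n - 1

    dist = np.zeros(15)
    for g in range(3):
        positions = np.flatnonzero(cls == g) + 1  # 1-based
        if positions.size == 0:
            continue
        k = positions.size
        for j, frac in enumerate((0.0, 0.25, 0.50, 0.75, 1.00)):
            idx = 0 if frac == 0.0 else int(np.ceil(frac * k)) - 1
            dist[g * 5 + j] = positions[idx] / n
    return np.concatenate([comp, trans, dist])


def ctd_descriptors(sequence: str) -> np.ndarray:
    """CTD over the 7 standard attributes: 7 x (3+3+15) = 147 entries."""
    return np.concatenate(
        [_ctd_single(sequence, CTD_GROUPS[attr]) for attr in CTD_GROUPS]
    )


class BuiltinProteinDescriptors:
    """AAC (20) + DPC (400) + CTD (147) = 567 sequence descriptors."""

    names = (
        tuple(f"aac_{aa}" for aa in AMINO_ACIDS)
        + tuple(f"dpc_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)
        + tuple(
            f"ctd_{attr}_{part}"
            for attr in CTD_GROUPS
            for part in (
                [f"c{g}" for g in (1, 2, 3)]
                + [f"t{p}" for p in ("12", "13", "23")]
                + [f"d{g}_{q}" for g in (1, 2, 3) for q in (0, 25, 50, 75, 100)]
            )
        )
    )

    def compute(self, sequence: str) -> np.ndarray:
        seq = _clean(sequence)
        if len(seq) < 2:
            raise ProteinDescriptorError(
                "descriptors require >= 2 standard residues "
                f"(got {len(seq)} after skipping non-standard ones)"
            )
        return np.concatenate(
            [
                amino_acid_composition(seq),
                dipeptide_composition(seq),
                ctd_descriptors(seq),
            ]
        )


DEFAULT_PROTEIN_PROVIDER = BuiltinProteinDescriptors()


def compute_protein_descriptors(sequence: str, provider=None) -> np.ndarray:
    """Descriptor vector for one sequence per the provider contract.

    Computed on the raw sequence (never the padded encoding), so the result
    is invariant to any downstream padding or truncation choices.
    """
    provider = provider or DEFAULT_PROTEIN_PROVIDER
    vec = np.asarray(provider.compute(sequence), dtype=np.float64)
    if vec.ndim != 1 or vec.shape[0] != len(provider.names):
        raise ProteinDescriptorError(
            f"provider returned width {vec.shape} but declares {len(provider.names)} names"
        )
    return vec
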
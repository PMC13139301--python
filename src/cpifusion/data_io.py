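"""Readers, writers and the core dataset container for CPI affinity tables.

A compound-protein interaction (CPI) dataset links small molecules (SMILES)
to protein targets (amino-acid sequences) through scalar affinity labels.
Two label scales are supported: the consolidated kinase-inhibitor KIBA score
and pEC50 = -log10(EC50 in molar).  All interactions in one dataset share a
single scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Placeholder for any non-standard residue (B, Z, U, O, J, ...).
UNKNOWN_RESIDUE = "X"

VALID_SCALES = ("kiba", "pEC50")

#: Conversion factors from concentration units to molar.
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "M": 1.0}


class CPIError(Exception):
    """Base class for dataset errors."""


class SchemaError(CPIError):
    """A required column is missing or a configuration value is invalid."""


class RowParseError(CPIError):
    """A data row could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str

    def __post_init__(self):
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.smiles:
            raise ValueError(f"compound {self.compound_id!r}: smiles must be non-empty")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {UNKNOWN_RESIDUE}
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: characters {sorted(bad)} outside "
                f"the declared alphabet (20 amino acids + {UNKNOWN_RESIDUE!r})"
            )


@dataclass(frozen=True)
class InteractionRecord:
    compound_id: str
    protein_id: str
    affinity: float
    scale_tag: str = "kiba"

    def __post_init__(self):
        if not math.isfinite(self.affinity):
            raise ValueError(
                f"interaction ({self.compound_id}, {self.protein_id}): "
                "affinity must be finite"
            )
        if self.scale_tag not in VALID_SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")


@dataclass
class CPIDataset:
    """Compounds, proteins and affinity-labelled interactions.

    Invariants checked at construction: unique entity ids, referential
    integrity of every interaction, no duplicate (compound, protein) pairs,
    a single shared affinity scale.
    """

    compounds: list[CompoundRecord] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self):
        self._compound_index = {c.compound_id: c for c in self.compounds}
        self._protein_index = {p.protein_id: p for p in self.proteins}
        if len(self._compound_index) != len(self.compounds):
            raise ValueError("duplicate compound_id in dataset")
        if len(self._protein_index) != len(self.proteins):
            raise ValueError("duplicate protein_id in dataset")
        seen_pairs = set()
        scales = set()
        for it in self.interactions:
            if it.compound_id not in self._compound_index:
                raise ValueError(f"interaction references unknown compound {it.compound_id!r}")
            if it.protein_id not in self._protein_index:
                raise ValueError(f"interaction references unknown protein {it.protein_id!r}")
            pair = (it.compound_id, it.protein_id)
            if pair in seen_pairs:
                raise ValueError(f"duplicate interaction pair {pair}")
            seen_pairs.add(pair)
            scales.add(it.scale_tag)
        if len(scales) > 1:
            raise ValueError(f"mixed affinity scales in one dataset: {sorted(scales)}")

    # -- accessors -------------------------------------------------------
    def compound(self, compound_id: str) -> CompoundRecord:
        return self._compound_index[compound_id]

    def protein(self, protein_id: str) -> ProteinRecord:
        return self._protein_index[protein_id]

    @property
    def scale_tag(self) -> str | None:
        return self.interactions[0].scale_tag if self.interactions else None

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def affinities(self) -> list[float]:
        return [it.affinity for it in self.interactions]

    def to_frame(self) -> pd.DataFrame:
        """Interactions as a tidy table with smiles and sequence joined in."""
        rows = [
            {
                "compound_id": it.compound_id,
                "smiles": self.compound(it.compound_id).smiles,
                "protein_id": it.protein_id,
                "sequence": self.protein(it.protein_id).sequence,
                "affinity": it.affinity,
            }
            for it in self.interactions
        ]
        return pd.DataFrame(
            rows, columns=["compound_id", "smiles", "protein_id", "sequence", "affinity"]
        )


DEFAULT_SCHEMA = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "protein_id": "protein_id",
    "sequence": "sequence",
    "affinity": "affinity",
}


def _normalize_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    return "".join(c if c in AMINO_ACIDS else UNKNOWN_RESIDUE for c in seq)


def _assemble_dataset(df: pd.DataFrame, scale_tag: str) -> CPIDataset:
    """Build a CPIDataset from a normalized frame with canonical columns.

    Duplicate (compound, protein) pairs are collapsed keeping the first
    occurrence; the number dropped is logged.  Entity ids missing from the
    table are synthesized from the order of first appearance.
    """
    n_before = len(df)
    df = df.drop_duplicates(subset=["compound_id", "protein_id"], keep="first")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d duplicate (compound, protein) rows (kept first)", n_dropped)

    compounds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    for row in df.itertuples(index=False):
        prev = compounds.setdefault(row.compound_id, row.smiles)
        if prev != row.smiles:
            raise RowParseError(
                f"compound_id {row.compound_id!r} maps to conflicting SMILES"
            )
        prev = proteins.setdefault(row.protein_id, row.sequence)
        if prev != row.sequence:
            raise RowParseError(
                f"protein_id {row.protein_id!r} maps to conflicting sequences"
            )

    return CPIDataset(
        compounds=[CompoundRecord(cid, smi) for cid, smi in compounds.items()],
        proteins=[ProteinRecord(pid, seq) for pid, seq in proteins.items()],
        interactions=[
            InteractionRecord(r.compound_id, r.protein_id, float(r.affinity), scale_tag)
            for r in df.itertuples(index=False)
        ],
    )


def _read_table(path, schema, delimiter) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = {"smiles", "sequence", "affinity"}
    missing = [mapping[k] for k in sorted(required) if mapping[k] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    out = pd.DataFrame()
    out["smiles"] = df[mapping["smiles"]].str.strip()
    out["sequence"] = df[mapping["sequence"]].map(_normalize_sequence)
    out["affinity_raw"] = df[mapping["affinity"]]

    # Entity id columns are optional: synthesize stable ids when absent.
    if mapping["compound_id"] in df.columns:
        out["compound_id"] = df[mapping["compound_id"]].str.strip()
    else:
        codes = {s: f"C{i + 1:05d}" for i, s in enumerate(dict.fromkeys(out["smiles"]))}
        out["compound_id"] = out["smiles"].map(codes)
    if mapping["protein_id"] in df.columns:
        out["protein_id"] = df[mapping["protein_id"]].str.strip()
    else:
        codes = {s: f"P{i + 1:05d}" for i, s in enumerate(dict.fromkeys(out["sequence"]))}
        out["protein_id"] = out["sequence"].map(codes)
    return out


def _parse_affinity(out: pd.DataFrame) -> pd.Series:
    values = pd.to_numeric(out["affinity_raw"], errors="coerce")
    bad = values.isna() | ~values.map(math.isfinite)
    if bad.any():
        i = int(bad.idxmax())
        raise RowParseError(
            f"unparseable affinity value {out['affinity_raw'].iloc[i]!r}",
            line=i + 2,  # +1 header, +1 one-based
        )
    return values


def load_cpi_table(path, schema=None, delimiter=",", scale_tag="kiba") -> CPIDataset:
    """Load a delimited CPI table into a validated :class:`CPIDataset`.

    Parameters
    ----------
    path : path-like
        CSV (or, with ``delimiter='\\t'``, TSV) file with a header row.
    schema : dict, optional
        Maps the canonical roles {compound_id, smiles, protein_id, sequence,
        affinity} to the file's column names.  Id columns may be absent from
        the file, in which case ids are synthesized per unique structure.
    scale_tag : {"kiba", "pEC50"}
        Scale of the affinity column as stored in the file.
    """
    if scale_tag not in VALID_SCALES:
        raise SchemaError(f"unknown scale_tag {scale_tag!r}")
    out = _read_table(path, schema, delimiter)
    if len(out) == 0:
        return CPIDataset()
    out["affinity"] = _parse_affinity(out)
    return _assemble_dataset(out, scale_tag)


def pec50_from_concentration(value: float, units: str) -> float:
    """pEC50 = -log10(EC50 in molar). Strictly decreasing in EC50."""
    if units == "pEC50":
        return float(value)
    if units not in _UNIT_TO_MOLAR:
        raise SchemaError(f"unknown units {units!r}; expected nM, uM, M or pEC50")
    if value <= 0:
        raise ValueError(f"concentration must be strictly positive, got {value}")
    return -math.log10(value * _UNIT_TO_MOLAR[units])


def load_activity_csv(path, value_column, value_units, schema=None, delimiter=",") -> CPIDataset:
    """Load an EC50-style activity table, converting labels to pEC50.

    ``value_units`` declares the units of ``value_column``: a concentration
    (nM, uM, M; strictly positive) or already-transformed pEC50.
    """
    if value_units not in set(_UNIT_TO_MOLAR) | {"pEC50"}:
        raise SchemaError(f"unknown units {value_units!r}; expected nM, uM, M or pEC50")
    mapping = dict(schema or {})
    mapping["affinity"] = value_column
    out = _read_table(path, mapping, delimiter)
    if len(out) == 0:
        return CPIDataset()
    raw = _parse_affinity(out)
    if value_units != "pEC50":
        nonpos = raw <= 0
        if nonpos.any():
            i = int(nonpos.idxmax())
            raise RowParseError(
                f"non-positive concentration {raw.iloc[i]}", line=i + 2
            )
    out["affinity"] = [pec50_from_concentration(v, value_units) for v in raw]
    return _assemble_dataset(out, "pEC50")


# -- predictions -------------------------------------------------------------

def write_predictions(records, path) -> None:
    """Write (compound_id, protein_id, predicted_affinity) rows as CSV.

    Full float precision is preserved so that a write/read round trip is
    exact.  Empty input is an error rather than an empty file.
    """
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty prediction table")
    df = pd.DataFrame(records, columns=["compound_id", "protein_id", "predicted_affinity"])
    df.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "protein_id": str})
    missing = [c for c in ("compound_id", "protein_id", "predicted_affinity") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing prediction columns {missing}")
    return df


# -- auxiliary entity formats ------------------------------------------------

def read_smi(path) -> list[CompoundRecord]:
    """Read a SMI file: one SMILES per line, optional whitespace-separated id."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"C{i:05d}"
            records.append(CompoundRecord(cid, smiles))
    return records


def write_smi(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.compound_id}\n")


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA, normalizing residues to the alphabet."""
    return [
        ProteinRecord(rec.id, _normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
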
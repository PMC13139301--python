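"""Synthetic CPI datasets with a planted local+global interaction signal.

The generator emulates the premise the model architecture is built on:
affinity depends jointly on a *local* match (a compound substructure motif
meeting a protein sequence motif) and a *global* physicochemical term (the
product of standardized molecular weight and protein hydrophobic fraction):

    y = b + w1 * 1[S in compound] * 1[M in protein]
          + w2 * z(MW_compound) * z(hydrophobic_fraction_protein) + eps,
    eps ~ Normal(0, sigma^2)

The motif term is invisible to the global descriptor heads alone and the
MW x hydrophobicity term is invisible to short local windows, so learning
the signal exercises all four heads.  SMILES are assembled from a fixed
fragment grammar (alkyl chains, benzene, amide linkers, a carboxyl cap) so
every generated structure is chemically valid and parseable.

Ground-truth signal components are returned alongside the dataset so tests
can verify the formula exactly at sigma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .data_io import AMINO_ACIDS, CompoundRecord, CPIDataset, InteractionRecord, ProteinRecord

#: Hydrophobic residues used for the protein global property.
HYDROPHOBIC_RESIDUES = set("AILMFWVY")

# Fragment grammar.  No fragment (or fragment junction) can spell the
# carboxyl motif, so motif presence is controlled solely by the cap.
_CHAIN_STARTS = ("C", "CC", "CCC", "CCCC")
_MIDDLE_FRAGMENTS = ("C", "CC", "CCC", "c1ccccc1", "C(=O)NC", "C(C)C")
_CARBOXYL_CAP = "C(=O)O"


@dataclass
class SignalSpec:
    """Planted-signal parameters; defaults define the standard benchmark task."""

    compound_motif: str = _CARBOXYL_CAP
    protein_motif: str = "HKWYR"  # 5-mer, vanishingly rare by chance
    w1: float = 2.0  # local motif-match weight
    w2: float = 1.0  # global MW x hydrophobicity weight
    sigma: float = 0.25  # noise standard deviation
    b: float = 5.0  # base affinity level (pEC50-like scale)

    def __post_init__(self):
        for name in ("w1", "w2", "b"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def generate_compounds(n: int, seed: int, motif: str = _CARBOXYL_CAP) -> pd.DataFrame:
    """n valid SMILES from the fragment grammar; about half carry the motif.

    Returns a frame with columns compound_id, smiles, has_motif, mw.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 compounds, got {n}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        parts = [rng.choice(_CHAIN_STARTS)]
        for _ in range(rng.integers(1, 5)):
            parts.append(rng.choice(_MIDDLE_FRAGMENTS))
        if rng.random() < 0.5:
            parts.append(motif)
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees validity; fail loudly if broken
            raise RuntimeError(f"fragment grammar produced invalid SMILES {smiles!r}")
        rows.append(
            {
                "compound_id": f"SC{i + 1:05d}",
                "smiles": smiles,
                "has_motif": motif in smiles,
                "mw": Descriptors.MolWt(mol),
            }
        )
    return pd.DataFrame(rows)


def generate_proteins(
    n: int,
    length_range: tuple[int, int] = (50, 200),
    seed: int = 0,
    motif: str = "HKWYR",
) -> pd.DataFrame:
    """n uniform-random sequences; about half get the motif inserted.

    Returns a frame with columns protein_id, sequence, has_motif,
    hydrophobic_fraction.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 proteins, got {n}")
    lo, hi = length_range
    if not (10 <= lo <= hi <= 2000):
        raise ValueError(f"length_range must satisfy 10 <= lo <= hi <= 2000, got {length_range}")
    if not (len(motif) >= 1 and set(motif) <= set(AMINO_ACIDS)):
        raise ValueError("protein motif must be a non-empty standard-residue string")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    rows = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length))
        if rng.random() < 0.5:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        rows.append(
            {
                "protein_id": f"SP{i + 1:05d}",
                "sequence": seq,
                "has_motif": motif in seq,
                "hydrophobic_fraction": sum(c in HYDROPHOBIC_RESIDUES for c in seq) / len(seq),
            }
        )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cpi_dataset(
    n_compounds: int,
    n_proteins: int,
    density: float,
    spec: SignalSpec | None = None,
    seed: int = 0,
    length_range: tuple[int, int] = (50, 200),
    scale_tag: str = "pEC50",
) -> tuple[CPIDataset, dict[str, pd.DataFrame]]:
    """Sample floor(density * n_c * n_p) pairs with planted-signal affinities.

    Returns the dataset plus ground-truth metadata frames ("compounds",
    "proteins", "interactions"); the interactions frame stores the local
    term, global term and noise of every label so oracle tests can
    recompute y exactly.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    spec = spec or SignalSpec()
    rng = np.random.default_rng(seed)
    comp = generate_compounds(n_compounds, seed=int(rng.integers(2**31)), motif=spec.compound_motif)
    prot = generate_proteins(
        n_proteins, length_range=length_range, seed=int(rng.integers(2**31)),
        motif=spec.protein_motif,
    )
    comp["z_mw"] = _zscore(comp["mw"].to_numpy())
    prot["z_hydro"] = _zscore(prot["hydrophobic_fraction"].to_numpy())

    n_pairs = int(np.floor(density * n_compounds * n_proteins))
    flat = rng.choice(n_compounds * n_proteins, size=n_pairs, replace=False)
    ci, pi = np.unravel_index(flat, (n_compounds, n_proteins))

    local = comp["has_motif"].to_numpy()[ci] & prot["has_motif"].to_numpy()[pi]
    global_term = comp["z_mw"].to_numpy()[ci] * prot["z_hydro"].to_numpy()[pi]
    noise = rng.normal(0.0, spec.sigma, size=n_pairs) if spec.sigma > 0 else np.zeros(n_pairs)
    y = spec.b + spec.w1 * local.astype(float) + spec.w2 * global_term + noise

    inter = pd.DataFrame(
        {
            "compound_id": comp["compound_id"].to_numpy()[ci],
            "protein_id": prot["protein_id"].to_numpy()[pi],
            "affinity": y,
            "local_term": local.astype(float),
            "global_term": global_term,
            "noise": noise,
        }
    )
    dataset = CPIDataset(
        compounds=[CompoundRecord(r.compound_id, r.smiles) for r in comp.itertuples()],
        proteins=[ProteinRecord(r.protein_id, r.sequence) for r in prot.itertuples()],
        interactions=[
            InteractionRecord(r.compound_id, r.protein_id, float(r.affinity), scale_tag)
            for r in inter.itertuples()
        ],
    )
    return dataset, {"compounds": comp, "proteins": prot, "interactions": inter}


# --------------------------------------------------------------------------
# standard benchmark tasks
# --------------------------------------------------------------------------

def source_task_spec() -> SignalSpec:
    """The large pretraining task: the default planted signal."""
    return SignalSpec()


def target_task_spec() -> SignalSpec:
    """The small transfer-target task: same motifs, shifted level and weights
    (a related but not identical structure-activity landscape)."""
    return SignalSpec(b=6.5, w1=1.2, w2=0.6, sigma=0.25)


def generate_transfer_tasks(
    seed: int,
    n_source_compounds: int = 200,
    n_source_proteins: int = 20,
    source_density: float = 0.5,
    n_target_compounds: int = 35,
    n_target_proteins: int = 14,
    target_density: float = 0.5,
):
    """Source and target datasets for the desk-scale transfer benchmark.

    Defaults give ~2,000 source pairs and exactly 245 target pairs (the
    size of a small single-target bioactivity set).
    """
    source, source_meta = generate_cpi_dataset(
        n_source_compounds, n_source_proteins, source_density,
        spec=source_task_spec(), seed=seed,
    )
    target, target_meta = generate_cpi_dataset(
        n_target_compounds, n_target_proteins, target_density,
        spec=target_task_spec(), seed=seed + 1,
    )
    return (source, source_meta), (target, target_meta)
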
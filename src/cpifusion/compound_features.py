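"""Compound representations for the two compound heads of the model.

Local head input: character-level label encoding of the SMILES string,
truncated/zero-padded to exactly 100 positions (0 = padding).

Global head input: a 1,024-bit ECFP4 (Morgan radius-2) fingerprint
concatenated with a molecular-descriptor vector.  Descriptor columns with
any null/non-finite value or zero variance on the training set are dropped
and the survivors z-scored by a postprocessor fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors surface as exceptions

SMILES_ENCODING_LENGTH = 100
FINGERPRINT_BITS = 1024
_MORGAN_RADIUS = 2  # ECFP4 = diameter 4


class FeaturizationError(Exception):
    """A structure could not be featurized; carries the compound id if known."""

    def __init__(self, message: str, compound_id: str | None = None):
        super().__init__(message if compound_id is None else f"{compound_id}: {message}")
        self.compound_id = compound_id


@dataclass
class SmilesVocabulary:
    """Injective character -> positive-integer map; 0 reserved for padding.

    Indices are assigned in sorted character order starting at 1, and the
    UNKNOWN index follows the last assigned character, so two corpora with
    the same character set yield identical vocabularies.
    """

    index: dict[str, int]
    unknown_index: int

    @property
    def size(self) -> int:
        """Largest assigned index (UNKNOWN included); valid ids are 0..size."""
        return self.unknown_index

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for ch, i in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{ch}\t{i}\n")
            fh.write(f"<UNK>\t{self.unknown_index}\n")

    @classmethod
    def load(cls, path) -> "SmilesVocabulary":
        index, unknown = {}, None
        with open(path) as fh:
            for line in fh:
                if not line.rstrip("\n"):
                    continue
                ch, i = line.rstrip("\n").split("\t")
                if ch == "<UNK>":
                    unknown = int(i)
                else:
                    index[ch] = int(i)
        if unknown is None:
            raise ValueError(f"{path}: vocabulary file lacks an <UNK> entry")
        return cls(index=index, unknown_index=unknown)


def build_vocabulary(smiles_corpus) -> SmilesVocabulary:
    """Label-encoding vocabulary over every character occurring in the corpus."""
    chars = sorted({ch for smi in smiles_corpus for ch in smi})
    if not chars:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    index = {ch: i for i, ch in enumerate(chars, start=1)}
    return SmilesVocabulary(index=index, unknown_index=len(chars) + 1)


def encode_smiles(smiles: str, vocab: SmilesVocabulary,
                  length: int = SMILES_ENCODING_LENGTH) -> np.ndarray:
    """Character-level label encoding, truncated/zero-padded to ``length``.

    The string is encoded as written (no canonicalization): two-character
    element symbols such as Cl are split into separate tokens.
    """
    if not smiles:
        raise ValueError("cannot encode an empty SMILES string")
    out = np.zeros(length, dtype=np.int64)
    unseen = set()
    for pos, ch in enumerate(smiles[:length]):
        idx = vocab.index.get(ch)
        if idx is None:
            unseen.add(ch)
            idx = vocab.unknown_index
        out[pos] = idx
    if unseen:
        logger.warning("characters %s not in vocabulary; mapped to UNKNOWN", sorted(unseen))
    return out


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES {smiles!r}", compound_id)
    return mol


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=_MORGAN_RADIUS, fpSize=FINGERPRINT_BITS
)


def compute_ecfp4(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """ECFP4 fingerprint folded to 1,024 bits.

    Depends only on the molecular graph, so different spellings of the same
    molecule give identical bit vectors.
    """
    mol = _mol_from_smiles(smiles, compound_id)
    return _MORGAN_GEN.GetFingerprintAsNumPy(mol).astype(np.float32)


class MinimalCompoundDescriptors:
    """Built-in descriptor provider: counts and simple physicochemical terms.

    A deliberately small, dependency-light panel (RDKit-backed) sufficient
    for the global compound head; wider externally computed matrices can be
    supplied through the same provider contract (``names`` + ``compute``).
    The first entry is the heavy-atom count.
    """

    names = (
        "heavy_atom_count",
        "mol_weight",
        "exact_mol_weight",
        "ring_count",
        "aromatic_ring_count",
        "heteroatom_count",
        "fraction_aromatic_atoms",
        "h_bond_donors",
        "h_bond_acceptors",
        "clogp",
        "tpsa",
        "rotatable_bonds",
        "fraction_csp3",
        "n_nitrogen",
        "n_oxygen",
        "n_bonds",
        "formal_charge",
        "n_sp2_carbons",
        "graph_diameter",
        "mol_weight_per_heavy_atom",
    )

    def compute(self, smiles: str, compound_id: str | None = None) -> np.ndarray:
        mol = _mol_from_smiles(smiles, compound_id)
        n_heavy = mol.GetNumHeavyAtoms()
        n_aromatic = sum(a.GetIsAromatic() for a in mol.GetAtoms())
        values = [
            n_heavy,
            Descriptors.MolWt(mol),
            Descriptors.ExactMolWt(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            rdMolDescriptors.CalcNumHeteroatoms(mol),
            n_aromatic / n_heavy if n_heavy else np.nan,
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcFractionCSP3(mol),
            sum(a.GetAtomicNum() == 7 for a in mol.GetAtoms()),
            sum(a.GetAtomicNum() == 8 for a in mol.GetAtoms()),
            mol.GetNumBonds(),
            Chem.GetFormalCharge(mol),
            sum(
                a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP2
                for a in mol.GetAtoms()
            ),
            float(Chem.rdmolops.GetDistanceMatrix(mol).max()) if n_heavy > 1 else 0.0,
            Descriptors.MolWt(mol) / n_heavy if n_heavy else np.nan,
        ]
        return np.asarray(values, dtype=np.float64)


DEFAULT_COMPOUND_PROVIDER = MinimalCompoundDescriptors()


def compute_compound_descriptors(smiles: str, provider=None,
                                 compound_id: str | None = None) -> np.ndarray:
    """Descriptor vector per the provider contract; NaN marks non-computable."""
    provider = provider or DEFAULT_COMPOUND_PROVIDER
    vec = np.asarray(provider.compute(smiles, compound_id), dtype=np.float64)
    if vec.ndim != 1 or vec.shape[0] != len(provider.names):
        raise FeaturizationError(
            f"provider returned width {vec.shape} but declares {len(provider.names)} names",
            compound_id,
        )
    return vec


@dataclass
class FeaturePostprocessor:
    """Column mask + z-scoring fitted once on a training descriptor matrix.

    Columns containing any null/non-finite value, or with zero variance, on
    the training rows are dropped.  Survivors are standardized with the
    training mean/sd; non-finite values appearing in later (unseen) rows are
    imputed with the training mean, i.e. 0 after scaling.
    """

    kept_columns: np.ndarray | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    n_input_columns: int | None = None
    _fitted: bool = field(default=False, repr=False)

    def fit(self, matrix: np.ndarray) -> "FeaturePostprocessor":
        if self._fitted:
            raise RuntimeError("postprocessor is fitted exactly once on training data")
        X = np.asarray(matrix, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training matrix must be 2-D and non-empty")
        finite = np.isfinite(X).all(axis=0)
        std = np.zeros(X.shape[1])
        std[finite] = X[:, finite].std(axis=0)
        keep = finite & (std > 0)
        self.kept_columns = np.flatnonzero(keep)
        self.mean = X[:, self.kept_columns].mean(axis=0)
        self.std = std[self.kept_columns]
        self.n_input_columns = X.shape[1]
        self._fitted = True
        logger.info(
            "postprocessor kept %d/%d descriptor columns", keep.sum(), X.shape[1]
        )
        return self

    def refit_statistics(self, matrix: np.ndarray) -> None:
        """Refit mean/sd on a new training set, keeping the column identities.

        Used when transferring a model to a new dataset: the model's input
        width (the kept columns) is frozen, only the standardization
        statistics adapt.  Columns degenerate on the new data (non-finite or
        constant) retain their previous statistics.
        """
        if not self._fitted:
            raise RuntimeError("refit_statistics requires a fitted postprocessor")
        X = np.asarray(matrix, dtype=np.float64)[:, self.kept_columns]
        finite = np.isfinite(X).all(axis=0)
        std = np.zeros(X.shape[1])
        std[finite] = X[:, finite].std(axis=0)
        ok = finite & (std > 0)
        new_mean, new_std = self.mean.copy(), self.std.copy()
        new_mean[ok] = X[:, ok].mean(axis=0)
        new_std[ok] = std[ok]
        self.mean, self.std = new_mean, new_std

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("postprocessor must be fitted before transform")
        X = np.asarray(matrix, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_input_columns:
            raise ValueError(
                f"expected {self.n_input_columns} columns, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        Z = (X[:, self.kept_columns] - self.mean) / self.std
        Z[~np.isfinite(Z)] = 0.0  # training-mean imputation after scaling
        return Z.astype(np.float32)

    def fit_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self.fit(matrix).transform(matrix)

    @property
    def n_output_columns(self) -> int:
        if not self._fitted:
            raise RuntimeError("postprocessor not fitted")
        return len(self.kept_columns)


def fit_postprocessor(training_matrix: np.ndarray) -> FeaturePostprocessor:
    return FeaturePostprocessor().fit(training_matrix)


def apply_postprocessor(pp: FeaturePostprocessor, matrix: np.ndarray) -> np.ndarray:
    return pp.transform(matrix)
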
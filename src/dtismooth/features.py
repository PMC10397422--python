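"""Initial biological node features: drug fingerprints and protein 3-mers.

Drugs: SMILES are parsed with RDKit into binary Morgan (circular
substructure) fingerprints, then reduced to d dimensions with either a
single-hidden-layer autoencoder or a deterministic truncated SVD.

Targets: protein sequences are encoded by conjoint-triad style 3-mer
composition over a 4-letter chemical-category alphabet (non-polar,
polar-neutral, acidic, basic), giving 4^3 = 64 dimensions instead of the
20^3 = 8000 raw 3-mer space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD
from sklearn.neural_network import MLPRegressor

from .hbin import NodeCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_CATEGORIES",
    "DrugFeatureConfig",
    "FeatureMatrix",
    "MorganFingerprintEncoder",
    "FingerprintReducer",
    "ProteinKmerEncoder",
    "encode_drug_structures",
    "reduce_dimensionality",
    "encode_protein_sequences",
    "assemble_initial_features",
    "l2_normalize_rows",
]

# Conjoint grouping of the 20 standard residues by side-chain chemistry.
# Category sizes are 7 / 8 / 2 / 3.
_NON_POLAR = "GAVLIFP"
_POLAR_NEUTRAL = "WSYCMNQT"
_ACIDIC = "DE"
_BASIC = "KRH"

AMINO_CATEGORIES: dict[str, int] = {
    **{aa: 0 for aa in _NON_POLAR},
    **{aa: 1 for aa in _POLAR_NEUTRAL},
    **{aa: 2 for aa in _ACIDIC},
    **{aa: 3 for aa in _BASIC},
}

N_CATEGORIES = 4
KMER_DIM = N_CATEGORIES**3  # 64


@dataclass
class DrugFeatureConfig:
    """Settings for the drug branch of the feature pipeline."""

    fingerprint_kind: str = "morgan"
    n_bits: int = 1024
    radius: int = 2
    d: int = 64
    reducer: str = "autoencoder"  # or "truncated-svd"
    seed: int = 0
    epochs: int = 200

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("reduced dimension d must be positive")
        if self.d > self.n_bits:
            raise ValueError(f"d={self.d} exceeds fingerprint width {self.n_bits}")
        if self.reducer not in ("autoencoder", "truncated-svd"):
            raise ValueError(f"unknown reducer: {self.reducer!r}")


@dataclass(frozen=True)
class FeatureMatrix:
    """Stacked initial features C = [C_d; C_t], aligned with the catalog."""

    values: np.ndarray
    catalog: NodeCatalog

    @property
    def d(self) -> int:
        return self.values.shape[1]


class MorganFingerprintEncoder(BaseEstimator, TransformerMixin):
    """Binary circular-substructure fingerprints from SMILES strings.

    Stateless transformer: `fit` only validates parameters. Unparseable
    SMILES raise, naming the offending entry — a silent zero row would
    poison the downstream reducer.
    """

    def __init__(self, n_bits: int = 1024, radius: int = 2):
        self.n_bits = n_bits
        self.radius = radius

    def fit(self, X, y=None):
        if self.n_bits <= 0 or self.radius < 0:
            raise ValueError("n_bits must be positive and radius non-negative")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        out = np.zeros((len(X), self.n_bits), dtype=np.float64)
        for i, smiles in enumerate(X):
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"unparseable SMILES at row {i}: {smiles!r}")
            fp = gen.GetFingerprint(mol)
            out[i, list(fp.GetOnBits())] = 1.0
        return out


class FingerprintReducer(BaseEstimator, TransformerMixin):
    """Reduce wide binary fingerprints to a d-dimensional embedding.

    method="autoencoder": one hidden layer of width d, logistic encoder,
    linear decoder, squared-error reconstruction loss (an MLP trained to
    reproduce its input; the embedding is the hidden activation).
    method="truncated-svd": deterministic ARPACK truncated SVD, provided for
    bit-reproducible pipelines.
    """

    def __init__(
        self,
        d: int = 64,
        method: str = "autoencoder",
        seed: int = 0,
        epochs: int = 200,
    ):
        self.d = d
        self.method = method
        self.seed = seed
        self.epochs = epochs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("reducer needs a 2-D matrix with at least 2 rows")
        if self.d > X.shape[1]:
            raise ValueError(f"d={self.d} exceeds input width {X.shape[1]}")
        if self.method == "truncated-svd":
            # Exact dense SVD: deterministic, and well defined even when d
            # exceeds the number of molecules (extra dimensions are zero,
            # since the matrix rank is at most min(n_rows, n_bits)).
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            self._projection = np.zeros((X.shape[1], self.d))
            rank = min(self.d, vt.shape[0])
            self._projection[:, :rank] = vt[:rank].T
        elif self.method == "autoencoder":
            self._ae = MLPRegressor(
                hidden_layer_sizes=(self.d,),
                activation="logistic",
                solver="adam",
                max_iter=self.epochs,
                random_state=self.seed,
                tol=0.0,
                n_iter_no_change=self.epochs,
            )
            import warnings

            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                self._ae.fit(X, X)
            self.loss_curve_ = list(self._ae.loss_curve_)
            if self.loss_curve_ and self.loss_curve_[-1] > self.loss_curve_[0]:
                logger.warning(
                    "autoencoder did not improve on its initial loss "
                    "(%.4g -> %.4g); returning best iterate",
                    self.loss_curve_[0],
                    self.loss_curve_[-1],
                )
        else:
            raise ValueError(f"unknown reducer method: {self.method!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.method == "truncated-svd":
            return X @ self._projection
        # Hidden-layer activation of the fitted autoencoder.
        z = X @ self._ae.coefs_[0] + self._ae.intercepts_[0]
        return 1.0 / (1.0 + np.exp(-z))


class ProteinKmerEncoder(BaseEstimator, TransformerMixin):
    """3-mer composition over the 4 chemical categories (64 dimensions).

    Sliding windows of three consecutive residues (stride 1) are mapped to
    the index c1*16 + c2*4 + c3 of their category triple. Residues outside
    the 20-letter alphabet (X, B, Z, U, *, ...) are dropped before windowing.
    With normalize=True (default) counts become frequencies summing to 1.
    """

    def __init__(self, normalize: bool = True):
        self.normalize = normalize

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        out = np.zeros((len(X), KMER_DIM), dtype=np.float64)
        n_dropped = 0
        for i, seq in enumerate(X):
            seq = seq.upper()
            cats = [AMINO_CATEGORIES[aa] for aa in seq if aa in AMINO_CATEGORIES]
            n_dropped += len(seq) - len(cats)
            if len(cats) < 3:
                raise ValueError(
                    f"sequence at row {i} has fewer than 3 standard residues"
                )
            for a, b, c in zip(cats, cats[1:], cats[2:]):
                out[i, a * 16 + b * 4 + c] += 1.0
            if self.normalize:
                out[i] /= out[i].sum()
        if n_dropped:
            logger.info("dropped %d non-standard residues before windowing", n_dropped)
        return out


def encode_drug_structures(
    smiles: list[str], cfg: DrugFeatureConfig | None = None
) -> np.ndarray:
    """Binary fingerprint matrix (n_drugs x n_bits) from SMILES strings."""
    cfg = cfg or DrugFeatureConfig()
    return MorganFingerprintEncoder(n_bits=cfg.n_bits, radius=cfg.radius).fit_transform(
        smiles
    )


def reduce_dimensionality(
    raw: np.ndarray, cfg: DrugFeatureConfig | None = None
) -> np.ndarray:
    """Reduce raw fingerprints to the d-dimensional drug block C_d."""
    cfg = cfg or DrugFeatureConfig()
    reducer = FingerprintReducer(
        d=cfg.d, method=cfg.reducer, seed=cfg.seed, epochs=cfg.epochs
    )
    return reducer.fit_transform(raw)


def encode_protein_sequences(seqs: list[str], normalize: bool = True) -> np.ndarray:
    """Category 3-mer target block C_t (n_targets x 64)."""
    return ProteinKmerEncoder(normalize=normalize).fit_transform(seqs)


def assemble_initial_features(
    c_drugs: np.ndarray, c_targets: np.ndarray, catalog: NodeCatalog
) -> FeatureMatrix:
    """Stack C = [C_d; C_t] in global node order."""
    c_drugs = np.asarray(c_drugs, dtype=np.float64)
    c_targets = np.asarray(c_targets, dtype=np.float64)
    if c_drugs.shape[0] != catalog.n_drugs:
        raise ValueError(
            f"drug block has {c_drugs.shape[0]} rows, catalog lists {catalog.n_drugs}"
        )
    if c_targets.shape[0] != catalog.n_targets:
        raise ValueError(
            f"target block has {c_targets.shape[0]} rows, "
            f"catalog lists {catalog.n_targets}"
        )
    if c_drugs.shape[1] != c_targets.shape[1]:
        raise ValueError(
            f"feature width mismatch: drugs {c_drugs.shape[1]}, "
            f"targets {c_targets.shape[1]}"
        )
    return FeatureMatrix(values=np.vstack([c_drugs, c_targets]), catalog=catalog)


def l2_normalize_rows(C: np.ndarray) -> np.ndarray:
    """Scale each row to unit L2 norm (zero rows are left untouched).

    The drug block (autoencoder activations, entries ~0.5) and the target
    block (3-mer frequencies, entries ~1/64) live on scales ~30x apart;
    propagation on the shared graph would otherwise let the larger block
    drown the smaller one. Row normalization puts both node types on a
    common footing before smoothing.
    """
    C = np.asarray(C, dtype=np.float64)
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return C / norms
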
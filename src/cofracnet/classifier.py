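"""Pair classifier estimator, input assembly, cross-validation, co-training.

The model input is one row per protein: the zero-padded, sum-normalized
elution profile (200 columns) concatenated with the protein's FCGR vector
(256 columns), to which a trainable embedding of the same width is added
inside the network.  Pairs are scored from shared protein-level
representations, so labeled complex structure reaches every protein through
the embedding during training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .elution import ElutionMatrix
from .fcgr import FCGRMatrix
from .labels import PairLabelSet
from .metrics import classification_metrics
from .nn import ModelConfig, PairScoringNetwork

__all__ = [
    "assemble_input",
    "PPIClassifier",
    "cross_validate_ppi",
    "co_train",
]


def assemble_input(
    E_padded: ElutionMatrix,
    S: FCGRMatrix,
    C: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate elution and sequence features row-wise: [E_i | S_i + C_i].

    All three inputs must share one protein ordering; both blocks are
    expected in [0, 1] already (row-normalized profiles, max-normalized
    FCGR).  ``C`` defaults to zeros — during training the network adds its
    own trainable embedding instead.
    """
    if E_padded.protein_ids != S.protein_ids:
        offenders = sorted(
            set(E_padded.protein_ids) ^ set(S.protein_ids)
        ) or ["(same ids, different order)"]
        raise ValueError(f"protein id mismatch between inputs: {offenders[:10]}")
    if E_padded.padded_to is None:
        raise ValueError("elution matrix must be padded before assembly")
    E = E_padded.values
    seq = S.vectors
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.shape != seq.shape:
            raise ValueError("embedding shape does not match FCGR matrix")
        seq = seq + C
    return np.hstack([E, seq])


def _pair_indices(df: pd.DataFrame, protein_ids: list[str]) -> np.ndarray:
    index = {p: i for i, p in enumerate(protein_ids)}
    missing = sorted(
        set(df["protein_a"]).union(df["protein_b"]) - set(index)
    )
    if missing:
        raise ValueError(f"pairs reference unknown proteins: {missing[:10]}")
    return np.column_stack(
        [df["protein_a"].map(index).to_numpy(), df["protein_b"].map(index).to_numpy()]
    )


class PPIClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator over protein-pair index arrays.

    ``fit(X, y)`` takes X of shape (n_pairs, 2) holding row indices into the
    per-protein feature matrix (supplied once via ``features`` at fit time)
    and binary labels y.  Fitted attributes follow sklearn conventions
    (``network_``, ``classes_``, ``loss_history_``).
    """

    def __init__(
        self,
        n_filters: int = 32,
        kernel_width: int = 5,
        fc_sizes: tuple[int, int, int] | None = None,
        dropout_rate: float = 0.2,
        weight_decay: float = 1e-4,
        learning_rate: float = 1e-3,
        epochs: int = 100,
        batch_size: int = 128,
        seed: int = 0,
        symmetrize: str = "abs",
        use_embedding: bool = True,
        seq_offset: int = 200,
    ):
        self.n_filters = n_filters
        self.kernel_width = kernel_width
        self.fc_sizes = fc_sizes
        self.dropout_rate = dropout_rate
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.symmetrize = symmetrize
        self.use_embedding = use_embedding
        self.seq_offset = seq_offset

    def _config(self) -> ModelConfig:
        return ModelConfig(
            n_filters=self.n_filters,
            kernel_width=self.kernel_width,
            fc_sizes=self.fc_sizes,
            dropout_rate=self.dropout_rate,
            weight_decay=self.weight_decay,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
            symmetrize=self.symmetrize,
            use_embedding=self.use_embedding,
        )

    def fit(self, X, y, features: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.intp)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) index array")
        if features is None:
            features = getattr(self, "features_", None)
        if features is None:
            raise ValueError("per-protein feature matrix required (features=...)")
        self.features_ = np.asarray(features, dtype=float)
        self.classes_ = np.array([0, 1])
        self.network_ = PairScoringNetwork(
            n_proteins=self.features_.shape[0],
            input_len=self.features_.shape[1],
            seq_offset=self.seq_offset,
            config=self._config(),
        )
        self.network_.fit(self.features_, X, y)
        self.loss_history_ = list(self.network_.loss_history_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.column_stack([1 - scores, scores])

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise ValueError("classifier is not fitted")
        return self.network_.score_pairs(self.features_, np.asarray(X, dtype=np.intp))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_function(X) > threshold).astype(int)

    def protein_representations(self) -> np.ndarray:
        return self.network_.protein_representations(self.features_)


def cross_validate_ppi(
    features: np.ndarray,
    protein_ids: list[str],
    folds: PairLabelSet,
    config: ModelConfig | None = None,
    threshold: float = 0.5,
) -> tuple[PPIClassifier, pd.DataFrame]:
    """k-fold cross-validation over balanced labeled pairs.

    For each fold: train on the remaining folds, evaluate the held-out fold
    at the hard 0.5 threshold.  Returns a final classifier retrained on all
    folds together with the per-fold metric table (sensitivity, specificity,
    MCC, AUC, accuracy).
    """
    config = config or ModelConfig()
    df = folds.pairs
    labeled = df[df["fold"].notna() & df["label"].isin(["positive", "negative"])]
    if labeled.empty:
        raise ValueError("no labeled pairs with fold assignments")
    pairs = _pair_indices(labeled, protein_ids)
    y = (labeled["label"] == "positive").to_numpy().astype(int)
    fold_ids = labeled["fold"].to_numpy(dtype=int)

    def make_clf():
        return PPIClassifier(**{
            "n_filters": config.n_filters,
            "kernel_width": config.kernel_width,
            "fc_sizes": config.fc_sizes,
            "dropout_rate": config.dropout_rate,
            "weight_decay": config.weight_decay,
            "learning_rate": config.learning_rate,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "seed": config.seed,
            "symmetrize": config.symmetrize,
            "use_embedding": config.use_embedding,
        })

    records = []
    for fold in sorted(np.unique(fold_ids)):
        held = fold_ids == fold
        clf = make_clf().fit(pairs[~held], y[~held], features=features)
        scores = clf.decision_function(pairs[held])
        rec = classification_metrics(y[held], scores, threshold=threshold)
        rec["fold"] = int(fold)
        rec["n_test"] = int(held.sum())
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("fold")
    final = make_clf().fit(pairs, y, features=features)
    return final, table


def co_train(
    datasets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: ModelConfig | None = None,
) -> PairScoringNetwork:
    """Train one shared network on several datasets (embedding disabled).

    ``datasets`` holds (features, pairs, labels) triples whose feature
    matrices share a common width (profiles padded to one length).  Each
    training pair list is down-sampled (seeded, without replacement) to the
    size of the smallest, and minibatches are drawn round-robin across
    datasets within every epoch.
    """
    config = config or ModelConfig()
    if config.use_embedding:
        config = ModelConfig(**{**config.__dict__, "use_embedding": False})
    widths = {d[0].shape[1] for d in datasets}
    if len(widths) != 1:
        raise ValueError(f"incompatible input widths across datasets: {sorted(widths)}")
    rng = np.random.default_rng(config.seed)
    n_min = min(len(d[1]) for d in datasets)
    sampled = []
    for features, pairs, y in datasets:
        pairs = np.asarray(pairs, dtype=np.intp)
        y = np.asarray(y, dtype=float)
        sel = rng.permutation(len(pairs))[:n_min]
        sampled.append((np.asarray(features, dtype=float), pairs[sel], y[sel]))

    net = PairScoringNetwork(
        n_proteins=sampled[0][0].shape[0],
        input_len=widths.pop(),
        seq_offset=200,
        config=config,
    )
    net.pairs_per_dataset_ = [len(s[1]) for s in sampled]
    if len(sampled) == 1:
        # degenerate case: plain training without the embedding component
        features, pairs, y = sampled[0]
        return net.fit(features, pairs, y)
    train_rng = np.random.default_rng(net.rng.integers(2**31))
    bs = config.batch_size
    n_batches = int(np.ceil(n_min / bs))
    for epoch in range(config.epochs):
        orders = [train_rng.permutation(n_min) for _ in sampled]
        losses = []
        for b in range(n_batches):
            for (features, pairs, y), order in zip(sampled, orders):
                sel = order[b * bs: (b + 1) * bs]
                if sel.size == 0:
                    continue
                loss = net.train_step(features, pairs[sel], y[sel], train_rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"co-training loss diverged at epoch {epoch}"
                    )
                losses.append(loss)
        net.loss_history_.append(float(np.mean(losses)))
    net.fitted_ = True
    return net
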
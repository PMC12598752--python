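"""Reference complexes and positive / negative / experimental pair labels.

Protein pairs inside one reference complex are positive interactions; pairs
whose two proteins are complex members but share no complex are negative.
A nominally positive pair is reclassified negative when its two normalized
elution profiles never co-elute, i.e. when the per-fraction intensity
product never exceeds 0.01.  Every remaining pair of observed proteins is
"experimental": unlabeled, scored only at prediction time.  Training uses a
balanced (1:1) positive/negative subset split into cross-validation folds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elution import ElutionMatrix

__all__ = [
    "ComplexCatalog",
    "PairLabelSet",
    "load_complexes",
    "write_complexes",
    "derive_pair_labels",
    "make_folds",
    "COELUTION_PRODUCT_THRESHOLD",
]

#: a positive pair must reach a per-fraction profile product above this value
COELUTION_PRODUCT_THRESHOLD = 0.01


@dataclass
class ComplexCatalog:
    """Mapping from complex id to its member protein-id set."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.complexes = {k: frozenset(v) for k, v in self.complexes.items()}

    def __len__(self) -> int:
        return len(self.complexes)

    def members(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.complexes.values():
            out |= m
        return frozenset(out)

    def restrict(self, proteins) -> "ComplexCatalog":
        """Drop members absent from ``proteins``; keep non-empty complexes."""
        proteins = frozenset(proteins)
        kept = {
            cid: m & proteins
            for cid, m in self.complexes.items()
            if m & proteins
        }
        return ComplexCatalog(kept)

    def filter_min_size(self, min_size: int) -> "ComplexCatalog":
        return ComplexCatalog(
            {cid: m for cid, m in self.complexes.items() if len(m) >= min_size}
        )


@dataclass
class PairLabelSet:
    """Canonically ordered protein pairs with labels and optional folds."""

    pairs: pd.DataFrame  # columns: protein_a, protein_b, label[, fold]

    LABELS = ("positive", "negative", "experimental")

    def __post_init__(self) -> None:
        df = self.pairs
        required = {"protein_a", "protein_b", "label"}
        if not required <= set(df.columns):
            raise ValueError(f"pair table must have columns {sorted(required)}")
        if (df["protein_a"] >= df["protein_b"]).any():
            raise ValueError("pairs must be canonically ordered (a < b)")
        if df.duplicated(["protein_a", "protein_b"]).any():
            raise ValueError("duplicate pairs")
        bad = set(df["label"]) - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def subset(self, label: str) -> pd.DataFrame:
        return self.pairs[self.pairs["label"] == label]

    def counts(self) -> dict[str, int]:
        return self.pairs["label"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PairLabelSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str}))


def load_complexes(path, min_size: int = 3) -> ComplexCatalog:
    """Read a GMT-like membership file (complex_id TAB member TAB member ...).

    Complexes with fewer than ``min_size`` members (after within-complex
    deduplication) are removed; removal counts are reported via warning.
    """
    complexes: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = [f for f in line.rstrip("\n").split("\t") if f]
            if not fields:
                continue
            cid, members = fields[0], fields[1:]
            if cid in complexes:
                raise ValueError(f"{path}:{line_no}: duplicate complex id {cid!r}")
            if len(members) != len(set(members)):
                warnings.warn(
                    f"complex {cid!r} lists duplicate members; deduplicated"
                )
            complexes[cid] = frozenset(members)
    if not complexes:
        raise ValueError(f"{path}: no complexes found")
    kept = {cid: m for cid, m in complexes.items() if len(m) >= min_size}
    n_removed = len(complexes) - len(kept)
    if n_removed:
        warnings.warn(
            f"removed {n_removed} complexes with fewer than {min_size} members"
        )
    return ComplexCatalog(kept)


def write_complexes(catalog: ComplexCatalog, path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(catalog.complexes):
            members = sorted(catalog.complexes[cid])
            fh.write("\t".join([cid, *members]) + "\n")


def _coelutes(profile_a: np.ndarray, profile_b: np.ndarray) -> bool:
    return float(np.max(profile_a * profile_b)) > COELUTION_PRODUCT_THRESHOLD


def derive_pair_labels(catalog: ComplexCatalog, E: ElutionMatrix) -> PairLabelSet:
    """Label every unordered pair of proteins in the elution matrix.

    Sharing a complex takes precedence: a pair is negative only if both
    proteins are complex members yet share no complex.  Positives lacking
    any co-eluting fraction (max per-fraction product <= 0.01, computed on
    the normalized, un-padded profile region) are reclassified negative.
    """
    if not E.normalized:
        raise ValueError("derive_pair_labels requires a normalized elution matrix")
    catalog = catalog.restrict(E.protein_ids)
    membership: dict[str, set[str]] = {}
    for cid, members in catalog.complexes.items():
        for p in members:
            membership.setdefault(p, set()).add(cid)

    region = E.values[:, : E.original_fractions]
    index = {pid: i for i, pid in enumerate(E.protein_ids)}
    rows = []
    for a, b in itertools.combinations(sorted(E.protein_ids), 2):
        ca, cb = membership.get(a), membership.get(b)
        if ca and cb and (ca & cb):
            label = (
                "positive" if _coelutes(region[index[a]], region[index[b]]) else "negative"
            )
        elif ca and cb:
            label = "negative"
        else:
            label = "experimental"
        rows.append((a, b, label))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "label"])
    return PairLabelSet(df)


def make_folds(
    P: PairLabelSet,
    k: int = 5,
    seed: int = 0,
    mode: str = "cv",
    test_frac: float = 0.3,
) -> PairLabelSet:
    """Balance negatives 1:1 against positives and assign folds.

    ``cv`` mode partitions the balanced pairs into ``k`` disjoint folds;
    ``split`` mode makes a single train/test partition (fold 0 = train,
    fold 1 = test) with ``test_frac`` of the balanced pairs held out.
    Experimental pairs never receive a fold.
    """
    if mode not in {"cv", "split"}:
        raise ValueError("mode must be 'cv' or 'split'")
    rng = np.random.default_rng(seed)
    pos = P.subset("positive").copy()
    neg = P.subset("negative").copy()
    if len(pos) < k or len(neg) < k:
        raise ValueError(
            f"need at least {k} positives and negatives, have "
            f"{len(pos)} / {len(neg)}"
        )
    n = min(len(pos), len(neg))
    # down-sample the larger class (without replacement, seeded) to 1:1
    pos = pos.iloc[rng.permutation(len(pos))[:n]]
    neg = neg.iloc[rng.permutation(len(neg))[:n]]
    balanced = pd.concat([pos, neg], ignore_index=True)
    order = rng.permutation(len(balanced))
    if mode == "cv":
        folds = np.empty(len(balanced), dtype=int)
        folds[order] = np.arange(len(balanced)) % k
    else:
        n_test = int(round(test_frac * len(balanced)))
        folds = np.zeros(len(balanced), dtype=int)
        folds[order[:n_test]] = 1
    balanced["fold"] = folds
    out = P.pairs.merge(
        balanced[["protein_a", "protein_b", "fold"]],
        on=["protein_a", "protein_b"],
        how="left",
    )
    # unbalanced-away labeled pairs and experimental pairs stay fold-less
    out["fold"] = out["fold"].astype("Int64")
    keep = out["fold"].notna() | (out["label"] == "experimental")
    return PairLabelSet(out[keep].reset_index(drop=True))
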
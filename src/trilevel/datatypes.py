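"""Domain types shared by every pipeline stage.

The unit of analysis is a functional term (typically a Gene Ontology term)
represented at three molecular levels — promoter methylation, microRNA
expression and mRNA expression — each measured on its own platform as a
feature-by-sample matrix with two-class (tumor / normal) sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The three molecular levels, in fixed priority order (used for tie-breaks).
LEVELS: tuple[str, str, str] = ("methylation", "microRNA", "mRNA")

#: Class labels for samples.
TUMOR = "tumor"
NORMAL = "normal"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Iterable[str], what: str, where: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r} in {where}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One platform's feature-by-sample value matrix with two-class labels.

    Parameters
    ----------
    level : str
        One of ``"methylation"``, ``"microRNA"``, ``"mRNA"``.
    feature_ids, sample_ids : list of str
        Unique row / column identifiers.
    values : ndarray, shape (n_features, n_samples)
        Platform-native measurements (e.g. beta values, log-intensities).
        No missing values are allowed.
    labels : list of str
        Per-sample class, each ``"tumor"`` or ``"normal"``; both classes
        must be present.
    """

    level: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature id", f"{self.level} matrix")
        _check_unique(self.sample_ids, "sample id", f"{self.level} matrix")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(self.labels) != ns:
            raise ValidationError("one label per sample required")
        bad_labels = set(self.labels) - {TUMOR, NORMAL}
        if bad_labels:
            raise ValidationError(f"unknown class label(s) {sorted(bad_labels)!r}")
        if len(set(self.labels)) < 2:
            raise ValidationError("both classes (tumor and normal) must be present")
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def tumor_mask(self) -> np.ndarray:
        """Boolean mask over samples, True for tumor."""
        return np.array([lab == TUMOR for lab in self.labels])

    def restrict(self, feature_set: Iterable[str]) -> np.ndarray:
        """Sub-matrix for the features of `feature_set` present here, in row order.

        Raises :class:`ValidationError` if the intersection is empty.
        """
        wanted = set(feature_set)
        rows = [i for f, i in self._feature_index.items() if f in wanted]
        if not rows:
            raise ValidationError(
                f"feature set {sorted(wanted)[:5]}... shares no features with the "
                f"{self.level} matrix"
            )
        return self.values[sorted(rows), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class AnnotationMap:
    """Term -> member gene set map (GMT-style), with optional descriptions."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, members in self.terms.items():
            if not members:
                raise ValidationError(f"term {t!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass
class TargetPredictionTable:
    """microRNA -> target-gene predictions pooled from several tools.

    `frame` holds one record per (microRNA, gene, tool) triple; triples must
    be unique and every tool name must belong to `tool_universe`.
    """

    frame: pd.DataFrame  # columns: microRNA, gene, tool
    tool_universe: frozenset[str]

    COLUMNS = ("microRNA", "gene", "tool")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"prediction table lacks column(s) {missing}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if self.frame.duplicated().any():
            dup = self.frame[self.frame.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate prediction record ({dup['microRNA']}, {dup['gene']}, {dup['tool']})"
            )
        stray = set(self.frame["tool"]) - set(self.tool_universe)
        if stray:
            raise ValidationError(f"tool(s) {sorted(stray)} not in the declared tool universe")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TermLevelSets:
    """The three parallel member sets representing one functional term."""

    term_id: str
    methylation_genes: frozenset[str]
    mirnas: frozenset[str]
    mrna_genes: frozenset[str]

    def members(self, level: str) -> frozenset[str]:
        if level == "methylation":
            return self.methylation_genes
        if level == "microRNA":
            return self.mirnas
        if level == "mRNA":
            return self.mrna_genes
        raise ValidationError(f"unknown level {level!r}")


@dataclass
class ConfusionCounts:
    """LOOCV tallies with tumor as the positive class.

    TP/FP count samples predicted tumor (truly tumor / truly normal);
    TN/FN count samples predicted normal.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name.upper()} must be a nonnegative integer, got {v!r}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn
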
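"""Comprehensive quality index F via contribution-weighted PCA.

The four pharmacopoeia indicators (calycosin-glucoside, astragaloside
IV, total polysaccharides, aqueous extracts) are reduced by principal
component analysis; the principal components retained to reach a target
cumulative contribution rate are combined into a single linear scoring
function

    F = w . x,   w = sum_k lambda_k / trace * v_k

where v_k is the k-th eigenvector and lambda_k / trace its contribution
(variance fraction). Higher F means better integrated quality. A model
may alternatively be constructed from explicit published coefficients
(``CompositeModel.from_weights``), in which case scoring applies the
weights to raw indicator contents with no preprocessing transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import INDICATORS, IndicatorPanel, SampleRecord

logger = logging.getLogger(__name__)

#: Published composite-index coefficients for (calycosin-glucoside,
#: astragaloside IV, polysaccharides, extracts), applied to raw contents.
PUBLISHED_COMPOSITE_WEIGHTS: tuple[float, ...] = (43.563, 27.067, 6.978, -2.553)


@dataclass(frozen=True)
class CompositeModel:
    """A fitted (or explicitly specified) composite scoring function.

    Attributes
    ----------
    preprocessing : {"correlation", "covariance", "none"}
        "correlation" z-scores each column before the eigendecomposition
        (scale-invariant); "covariance" centres only; "none" marks an
        explicit-weights model scoring raw contents.
    retained_k : int
        Number of principal components combined into the weights.
    contributions : tuple of float
        Variance fraction of every PC, sorted descending; sums to 1.
    eigenvectors : tuple of tuple of float
        The ``retained_k`` unit eigenvectors (sign-fixed so each PC's
        largest-magnitude loading is positive).
    weights : tuple of float
        The combined scoring vector w.
    cumulative_contribution : float
        Sum of the retained contributions.
    column_means, column_scales : tuple of float
        Preprocessing transform applied before scoring.
    """

    preprocessing: str
    retained_k: int
    contributions: tuple[float, ...]
    eigenvectors: tuple[tuple[float, ...], ...]
    weights: tuple[float, ...]
    cumulative_contribution: float
    column_means: tuple[float, ...]
    column_scales: tuple[float, ...]
    indicator_names: tuple[str, ...] = field(default=INDICATORS)

    @classmethod
    def from_weights(
        cls,
        weights: Sequence[float],
        indicator_names: Sequence[str] = INDICATORS,
    ) -> "CompositeModel":
        """Build an explicit-weights model scoring raw indicator contents."""
        w = tuple(float(v) for v in weights)
        if len(w) != len(indicator_names):
            raise ValueError("one weight per indicator required")
        p = len(w)
        return cls(
            preprocessing="none",
            retained_k=0,
            contributions=(),
            eigenvectors=(),
            weights=w,
            cumulative_contribution=float("nan"),
            column_means=(0.0,) * p,
            column_scales=(1.0,) * p,
            indicator_names=tuple(indicator_names),
        )


def _as_matrix(indicators, names) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(indicators, pd.DataFrame):
        names = tuple(indicators.columns) if names is None else tuple(names)
        return indicators.to_numpy(dtype=float), names
    X = np.asarray(indicators, dtype=float)
    if X.ndim != 2:
        raise ValueError("indicator matrix must be 2-D (samples x indicators)")
    if names is None:
        names = INDICATORS if X.shape[1] == len(INDICATORS) else tuple(
            f"x{i + 1}" for i in range(X.shape[1])
        )
    return X, tuple(names)


def fit_composite(
    indicators,
    threshold: float = 0.85,
    preprocessing: str = "correlation",
    indicator_names: Sequence[str] | None = None,
) -> CompositeModel:
    """Fit the composite model on an n x p indicator matrix.

    The eigendecomposition runs on the correlation matrix by default
    (the four indicators live on scales three decades apart), or on the
    covariance matrix. The smallest k principal components whose
    cumulative contribution reaches ``threshold`` are retained, their
    signs fixed so each PC's largest-magnitude loading is positive, and
    combined as w = sum_k contribution_k * eigenvector_k.

    Raises
    ------
    ValueError
        n < p, or a zero-variance column (named in the message).
    """
    X, names = _as_matrix(indicators, indicator_names)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} samples to fit on {p} indicators, got {n}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if preprocessing not in ("correlation", "covariance"):
        raise ValueError(f"unknown preprocessing {preprocessing!r}")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = [names[j] for j in range(p) if sds[j] == 0]
    if dead:
        raise ValueError(f"zero-variance indicator column(s): {', '.join(dead)}")
    scales = sds if preprocessing == "correlation" else np.ones(p)

    Z = (X - means) / scales
    M = (Z.T @ Z) / (n - 1)  # correlation or covariance matrix
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    contributions = eigvals / eigvals.sum()
    cumulative = np.cumsum(contributions)
    k = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    k = min(k, p)

    retained = []
    for i in range(k):
        v = eigvecs[:, i]
        if v[np.argmax(np.abs(v))] < 0:  # deterministic sign across solvers
            v = -v
        retained.append(v)
    weights = np.zeros(p)
    for i, v in enumerate(retained):
        weights += contributions[i] * v

    return CompositeModel(
        preprocessing=preprocessing,
        retained_k=k,
        contributions=tuple(float(c) for c in contributions),
        eigenvectors=tuple(tuple(float(x) for x in v) for v in retained),
        weights=tuple(float(w) for w in weights),
        cumulative_contribution=float(cumulative[k - 1]),
        column_means=tuple(float(m) for m in means),
        column_scales=tuple(float(s) for s in scales),
        indicator_names=names,
    )


def score_composite(model: CompositeModel, panel) -> float:
    """Score one sample: F = w . x after the model's preprocessing transform.

    ``panel`` may be an :class:`IndicatorPanel` or a plain sequence in
    the model's indicator order. Explicit-weights models score raw
    values; fitted models centre (and scale, under correlation
    preprocessing) first.
    """
    if isinstance(panel, IndicatorPanel):
        x = np.array(panel.as_vector(), dtype=float)
    else:
        x = np.asarray(panel, dtype=float)
    if x.shape != (len(model.weights),):
        raise ValueError(
            f"panel has {x.size} values, model expects {len(model.weights)}"
        )
    z = (x - np.asarray(model.column_means)) / np.asarray(model.column_scales)
    return float(np.dot(model.weights, z))


@dataclass(frozen=True)
class CompositeReport:
    """Ranked F table plus optional per-group means and skip log."""

    scores: pd.DataFrame  # columns: sample_id, F (sorted F desc, id asc)
    group_means: pd.DataFrame | None
    skipped: tuple[str, ...]


def composite_report(
    model: CompositeModel,
    panels: Sequence[IndicatorPanel],
    samples: Sequence[SampleRecord] | None = None,
) -> CompositeReport:
    """Score a cohort and rank it by F (descending, sample_id breaking ties).

    When ``samples`` metadata is supplied, samples without a matching
    panel are skipped with a logged reason, and mean F per region and
    per cultivation class is tabulated alongside.
    """
    by_id = {p.sample_id: p for p in panels}
    skipped: list[str] = []
    rows = []
    if samples is not None:
        meta = {s.sample_id: s for s in samples}
        for s in samples:
            panel = by_id.get(s.sample_id)
            if panel is None:
                logger.warning("skip sample=%s reason=missing_indicator_panel", s.sample_id)
                skipped.append(s.sample_id)
                continue
            rows.append({"sample_id": s.sample_id, "F": score_composite(model, panel)})
    else:
        meta = {}
        rows = [
            {"sample_id": p.sample_id, "F": score_composite(model, p)} for p in panels
        ]
    scores = pd.DataFrame(rows, columns=["sample_id", "F"])
    if len(scores):
        scores = scores.sort_values(
            ["F", "sample_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    group_means = None
    if samples is not None and len(scores):
        joined = scores.assign(
            region=[meta[i].region for i in scores["sample_id"]],
            cultivation=[meta[i].cultivation for i in scores["sample_id"]],
        )
        parts = []
        for field_name in ("region", "cultivation"):
            g = joined.groupby(field_name)["F"].agg(["mean", "size"]).reset_index()
            g.insert(0, "grouping", field_name)
            g = g.rename(columns={field_name: "group", "mean": "mean_F", "size": "n"})
            parts.append(g)
        group_means = pd.concat(parts, ignore_index=True)
    return CompositeReport(
        scores=scores, group_means=group_means, skipped=tuple(skipped)
    )


def save_model(model: CompositeModel, path: str | Path) -> None:
    """Persist a model as a flat key=value text file."""
    lines = [
        f"preprocessing={model.preprocessing}",
        f"retained_k={model.retained_k}",
        f"cumulative_contribution={model.cumulative_contribution!r}",
        "indicator_names=" + ",".join(model.indicator_names),
        "contributions=" + ",".join(repr(c) for c in model.contributions),
        "weights=" + ",".join(repr(w) for w in model.weights),
        "column_means=" + ",".join(repr(m) for m in model.column_means),
        "column_scales=" + ",".join(repr(s) for s in model.column_scales),
    ]
    for i, v in enumerate(model.eigenvectors):
        lines.append(f"eigenvector_{i + 1}=" + ",".join(repr(x) for x in v))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> CompositeModel:
    """Inverse of :func:`save_model`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            kv[key] = value

    def floats(key: str) -> tuple[float, ...]:
        raw = kv.get(key, "")
        return tuple(float(v) for v in raw.split(",")) if raw else ()

    k = int(kv["retained_k"])
    return CompositeModel(
        preprocessing=kv["preprocessing"],
        retained_k=k,
        contributions=floats("contributions"),
        eigenvectors=tuple(floats(f"eigenvector_{i + 1}") for i in range(k)),
        weights=floats("weights"),
        cumulative_contribution=float(kv["cumulative_contribution"]),
        column_means=floats("column_means"),
        column_scales=floats("column_scales"),
        indicator_names=tuple(kv["indicator_names"].split(",")),
    )
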
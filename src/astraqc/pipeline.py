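"""End-to-end run: cohort -> sweetness -> composite index -> associations.

One call (or ``astraqc run`` from a shell) either ingests a pair of
sample/indicator CSVs or simulates a cohort from a
:class:`~astraqc.synthetic.CohortConfig`, then computes the sweetness
table, per-group summaries, the fitted (or explicit-weights) composite
index with its ranked F table, the four indicator-on-sweetness
regressions, and the full correlation matrix, writing every artifact as
CSV plus a JSON run manifest.

Numeric outputs are a pure function of the inputs and the seed:
re-running with the same seed reproduces every table byte for byte.
Wall-clock timestamps therefore go to the run log only, never into the
numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as aio
from .association import association_table, correlation_matrix
from .composite import (
    CompositeModel,
    CompositeReport,
    composite_report,
    fit_composite,
    save_model,
)
from .records import COMPONENTS, INDICATORS, IndicatorPanel, SampleRecord, group_summary
from .sweetness import SweetnessReference, sweetness_frame, sweetness_table
from .synthetic import CohortConfig, config_to_dict, generate_cohort, save_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineReport:
    """All pipeline artifacts plus run metadata."""

    samples: list[SampleRecord]
    panels: list[IndicatorPanel]
    sweetness: pd.DataFrame
    group_summaries: pd.DataFrame
    model: CompositeModel
    composite: CompositeReport
    associations: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def _summary_frame(
    samples: Sequence[SampleRecord], sweetness: pd.DataFrame, groupings: Sequence[str]
) -> pd.DataFrame:
    """Mean/SD of each component (mg/g) and of sweetness, per group."""
    sweet = dict(zip(sweetness["sample_id"], sweetness["sweetness_mg_eq_g"]))
    rows = []
    for grouping in groupings:
        for gs in group_summary(samples, by=[grouping]):
            row = {
                "grouping": grouping,
                "group": gs.key[grouping],
                "n": gs.n,
            }
            vals = np.array(
                [sweet[s.sample_id] for s in samples
                 if getattr(s, grouping) == gs.key[grouping]]
            )
            row["sweetness_mean"] = vals.mean()
            row["sweetness_sd"] = vals.std(ddof=1) if gs.n > 1 else np.nan
            for c in COMPONENTS:
                row[f"{c}_mean"] = gs.mean[c]
                row[f"{c}_sd"] = gs.sd[c] if gs.sd[c] is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@_stage("ingest")
def _load_inputs(samples_csv, indicators_csv):
    samples = aio.read_samples(samples_csv)
    panels = aio.read_indicators(indicators_csv) if indicators_csv else []
    return samples, panels


@_stage("simulate")
def _simulate(config: CohortConfig, reference):
    return generate_cohort(config, reference)


def run_pipeline(
    out_dir: str | Path,
    *,
    cohort_config: CohortConfig | None = None,
    samples_csv: str | Path | None = None,
    indicators_csv: str | Path | None = None,
    weights: Sequence[float] | None = None,
    preprocessing: str = "correlation",
    threshold: float = 0.85,
    reference: SweetnessReference | None = None,
) -> PipelineReport:
    """Run every stage and write all artifacts under ``out_dir``.

    Exactly one of ``cohort_config`` (simulate) or ``samples_csv`` +
    ``indicators_csv`` (ingest) must be given. ``weights`` switches the
    composite stage from fitting on the cohort's own indicator matrix to
    an explicit-weights model scoring raw contents.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("astraqc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(
            out,
            cohort_config=cohort_config,
            samples_csv=samples_csv,
            indicators_csv=indicators_csv,
            weights=weights,
            preprocessing=preprocessing,
            threshold=threshold,
            reference=reference,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(
    out: Path,
    *,
    cohort_config,
    samples_csv,
    indicators_csv,
    weights,
    preprocessing,
    threshold,
    reference,
) -> PipelineReport:
    logger.info("run started at %s", datetime.now(timezone.utc).isoformat())

    if (cohort_config is None) == (samples_csv is None):
        raise PipelineError(
            "stage 'config': provide either a cohort config (simulate) or "
            "a samples CSV (ingest), not both"
        )
    if cohort_config is not None:
        samples, panels = _simulate(cohort_config, reference)
        save_config(cohort_config, out / "config.yaml")
        config_hash = hashlib.sha256(
            json.dumps(config_to_dict(cohort_config), sort_keys=True).encode()
        ).hexdigest()
        seed = cohort_config.seed
    else:
        if indicators_csv is None:
            raise PipelineError(
                "stage 'ingest': composite stage requires an indicators CSV"
            )
        samples, panels = _load_inputs(samples_csv, indicators_csv)
        config_hash = hashlib.sha256(Path(samples_csv).read_bytes()).hexdigest()
        seed = None

    aio.write_samples(samples, out / "samples.csv")
    aio.write_indicators(panels, out / "indicators.csv")

    # sweetness stage
    try:
        results = sweetness_table(samples, reference)
    except Exception as exc:
        raise PipelineError(f"stage 'sweetness': {exc}") from exc
    sweet = sweetness_frame(results)
    sweet.to_csv(out / "sweetness.csv", index=False)

    summaries = _summary_frame(samples, sweet, groupings=("region", "growth_years"))
    summaries.to_csv(out / "group_summary.csv", index=False)

    # composite stage
    try:
        panel_frame = pd.DataFrame(
            [dict(zip(INDICATORS, p.as_vector())) for p in panels],
            index=[p.sample_id for p in panels],
        )
        if weights is not None:
            model = CompositeModel.from_weights(weights)
        else:
            model = fit_composite(
                panel_frame, threshold=threshold, preprocessing=preprocessing
            )
        comp = composite_report(model, panels, samples)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'composite': {exc}") from exc
    save_model(model, out / "composite_model.txt")
    comp.scores.to_csv(out / "f_scores.csv", index=False)
    if comp.group_means is not None:
        comp.group_means.to_csv(out / "f_group_means.csv", index=False)

    # association stage (over samples that carry a full panel)
    try:
        with_panels = [s.sample_id for s in samples if s.sample_id in panel_frame.index]
        ordered = panel_frame.loc[with_panels]
        x = (
            sweet.set_index("sample_id")
            .loc[with_panels, "sweetness_mg_eq_g"]
            .to_numpy()
        )
        assoc = association_table(x, ordered)
        corr = correlation_matrix(
            ordered.assign(sweetness=x)[["sweetness", *INDICATORS]]
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'association': {exc}") from exc
    assoc.to_csv(out / "association.csv", index=False)
    corr.to_csv(out / "correlation_matrix.csv")

    metadata = {
        "seed": seed,
        "config_hash": config_hash,
        "n_samples": len(samples),
        "n_scored": int(len(comp.scores)),
        "skipped": list(comp.skipped),
        "composite": {
            "preprocessing": model.preprocessing,
            "retained_k": model.retained_k,
            "cumulative_contribution": model.cumulative_contribution,
            "weights": list(model.weights),
        },
    }
    (out / "report.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("run finished at %s", datetime.now(timezone.utc).isoformat())

    return PipelineReport(
        samples=samples,
        panels=panels,
        sweetness=sweet,
        group_summaries=summaries,
        model=model,
        composite=comp,
        associations=assoc,
        correlations=corr,
        metadata=metadata,
    )


def compare_groups(report: PipelineReport, grouping: str) -> pd.DataFrame:
    """Group means of sweetness and F side by side, ordered by sweetness.

    ``grouping`` is any sample metadata field (``region``,
    ``cultivation``, ``growth_years``, ``species``). Rows are ordered by
    descending mean sweetness, the presentation used to compare regions
    and cultivation classes.
    """
    valid = ("species", "region", "growth_years", "cultivation")
    if grouping not in valid:
        raise ValueError(f"unknown grouping field {grouping!r}; expected one of {valid}")
    sweet = dict(
        zip(report.sweetness["sample_id"], report.sweetness["sweetness_mg_eq_g"])
    )
    f_by_id = dict(zip(report.composite.scores["sample_id"], report.composite.scores["F"]))
    rows: dict = {}
    for s in report.samples:
        key = getattr(s, grouping)
        rows.setdefault(key, {"sweetness": [], "F": []})
        rows[key]["sweetness"].append(sweet[s.sample_id])
        if s.sample_id in f_by_id:
            rows[key]["F"].append(f_by_id[s.sample_id])
    table = pd.DataFrame(
        [
            {
                "group": key,
                "n": len(v["sweetness"]),
                "mean_sweetness": float(np.mean(v["sweetness"])),
                "mean_F": float(np.mean(v["F"])) if v["F"] else np.nan,
            }
            for key, v in rows.items()
        ]
    )
    return table.sort_values(
        "mean_sweetness", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
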
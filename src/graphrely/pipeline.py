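"""End-to-end orchestration: simulate -> connect -> graph -> reliability.

`compute_outcomes` turns recordings into a tidy table of global graph
outcomes (CC, PL, SWI per participant/session/condition/band/estimator);
`reliability_analysis` turns that table into reliability, condition-
comparison and ANOVA tables shaped like the publication tables;
`run_pipeline` runs everything, writes CSVs and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    BandDefinition,
    ConnectivityStack,
    Recording,
    SpectralConfig,
    coherence,
    default_bands,
    epoch_signal,
    wpli,
)
from .graphs import (
    DegenerateStackError,
    aggregate_epochs,
    clustering_coefficient,
    normalize_stack,
    path_length,
    small_world_index,
)
from .reliability import (
    bootstrap_reliability_compare,
    icc_absolute_single,
    paired_t,
    rm_anova_2x2,
    sem_and_cov,
    DegenerateTableError,
)
from .synthetic import CouplingSpec, StudyDesign, TwoWayTable, default_coupling, generate_study

__all__ = ["PipelineConfig", "compute_outcomes", "reliability_analysis", "run_pipeline"]

logger = logging.getLogger("graphrely")

_ESTIMATORS = {"wpli": wpli, "coh": coherence}
_OUTCOMES = ("cc", "pl", "swi")


@dataclass
class PipelineConfig:
    """All knobs of one reproducible pipeline run."""

    bands: list[BandDefinition] = field(default_factory=default_bands)
    estimators: tuple[str, ...] = ("wpli", "coh")
    epoch_length: float = 8.0
    overlap: float = 4.0
    max_epochs: int = 50
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    aggregate_matrices: bool = False
    k_cycles: int = 1000
    n_boot_cov: int = 2000
    seed: int = 0
    design: StudyDesign | None = None
    coupling: list[CouplingSpec] | None = None

    def __post_init__(self) -> None:
        if not self.bands or not self.estimators:
            raise ValueError("need at least one band and one estimator")
        for est in self.estimators:
            if est not in _ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")

    def snapshot(self) -> dict:
        """JSON-serializable snapshot of the resolved configuration."""
        snap = {
            "bands": [{"name": b.name, "low": b.low, "high": b.high}
                      for b in self.bands],
            "estimators": list(self.estimators),
            "epoch_length": self.epoch_length,
            "overlap": self.overlap,
            "max_epochs": self.max_epochs,
            "spectral": asdict(self.spectral),
            "aggregate_matrices": self.aggregate_matrices,
            "k_cycles": self.k_cycles,
            "n_boot_cov": self.n_boot_cov,
            "seed": self.seed,
        }
        if self.design is not None:
            d = asdict(self.design)
            d["conditions"] = list(self.design.conditions)
            snap["design"] = d
        if self.coupling is not None:
            snap["coupling"] = [
                {"band": spec.band.name, "n_edges": len(spec.edges),
                 "noise_sd": spec.noise_sd,
                 "session_consistency": spec.session_consistency,
                 "condition_shift": spec.condition_shift,
                 "waveform": spec.waveform}
                for spec in self.coupling
            ]
        return snap


def _child_seed(seed: int, idx: int) -> int:
    return (seed * 1000003 + 7919 * (idx + 1)) % (2**31)


# ---------------------------------------------------------------------------
# recordings -> graph outcomes


def compute_outcomes(
    recordings: Sequence[Recording],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Tidy outcome table: one row per recording x estimator x band.

    Each recording is epoched, connectivity is estimated per epoch, the
    stack is min-max normalized, global CC/PL are computed per epoch and
    averaged, and SWI is derived from the epoch-averaged CC/PL across the
    configured bands.  With ``aggregate_matrices`` the epoch matrices are
    averaged first and a single graph is analyzed instead.
    """
    config = config or PipelineConfig()
    rows = []
    for rec in recordings:
        eset = epoch_signal(rec, config.epoch_length, config.overlap,
                            config.max_epochs)
        for est in config.estimators:
            cc_by_band: dict[str, float] = {}
            pl_by_band: dict[str, float] = {}
            for band in config.bands:
                stack = _ESTIMATORS[est](eset, band, config.spectral)
                if config.aggregate_matrices:
                    mean_mat = stack.matrices.mean(axis=0)[None, :, :]
                    stack = ConnectivityStack(
                        matrices=mean_mat, estimator=est, band=band,
                        channel_labels=stack.channel_labels,
                        participant_id=stack.participant_id,
                        session_id=stack.session_id,
                        condition=stack.condition,
                    )
                graphs = normalize_stack(stack)
                cc_e = [clustering_coefficient(g) for g in graphs]
                pl_e = [path_length(g) for g in graphs]
                cc, pl = aggregate_epochs(cc_e, pl_e)
                cc_by_band[band.name] = cc
                pl_by_band[band.name] = pl
            swi = (small_world_index(cc_by_band, pl_by_band)
                   if len(config.bands) >= 2
                   else {b: np.nan for b in cc_by_band})
            for band in config.bands:
                rows.append({
                    "participant": rec.participant_id,
                    "session": rec.session_id,
                    "condition": rec.condition,
                    "estimator": est,
                    "band": band.name,
                    "cc": cc_by_band[band.name],
                    "pl": pl_by_band[band.name],
                    "swi": swi[band.name],
                })
        logger.info("outcomes: %s/%s/%s done", rec.participant_id,
                    rec.session_id, rec.condition)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# graph outcomes -> reliability tables


def _two_way(outcomes: pd.DataFrame, est: str, band: str, outcome: str,
             condition: str) -> TwoWayTable:
    sub = outcomes[(outcomes.estimator == est) & (outcomes.band == band)
                   & (outcomes.condition == condition)]
    pivot = sub.pivot_table(index="participant", columns="session",
                            values=outcome, sort=True)
    pivot = pivot.reindex(sorted(pivot.columns), axis=1)
    if pivot.isna().any().any():
        raise DegenerateTableError(
            f"missing cells for {est}/{band}/{outcome}/{condition}"
        )
    return TwoWayTable(
        values=pivot.to_numpy(dtype=float), outcome_label=outcome,
        condition=condition, subject_ids=[str(i) for i in pivot.index],
        session_ids=[str(c) for c in pivot.columns],
    )


def reliability_analysis(
    outcomes: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Reliability, condition-comparison and ANOVA tables from tidy outcomes.

    Returns ``{"reliability": ..., "comparisons": ..., "anova": ...}``.
    The reliability table has one row per estimator x band x outcome x
    condition with per-session means/SDs, ICC [LB UB] + category, SEM,
    CoV% [LB UB] and the session paired t-test.  Comparisons hold the
    bootstrap Cohen's d of PRE vs POST reliability (ICC on the Fisher-z
    scale, CoV on the percent scale).  The ANOVA table has exercise,
    session and interaction effects per outcome.
    """
    config = config or PipelineConfig()
    conditions = list(dict.fromkeys(outcomes["condition"]))
    estimators = [e for e in config.estimators if e in set(outcomes.estimator)]
    bands = [b.name for b in config.bands if b.name in set(outcomes.band)]

    rel_rows, cmp_rows, anova_rows = [], [], []
    idx = 0
    for est in estimators:
        for band in bands:
            for outcome in _OUTCOMES:
                if outcome not in outcomes.columns:
                    continue
                if outcomes[outcome].isna().all():
                    logger.warning("outcome %r is undefined everywhere "
                                   "(e.g. SWI with one band): skipped", outcome)
                    continue
                tables = {}
                for cond in conditions:
                    tab = _two_way(outcomes, est, band, outcome, cond)
                    tables[cond] = tab
                    icc_res = icc_absolute_single(tab)
                    cov_res = sem_and_cov(
                        tab, icc_res.icc, n_boot=config.n_boot_cov,
                        seed=_child_seed(config.seed, idx),
                    )
                    idx += 1
                    try:
                        t, p = paired_t(tab.values[:, 0], tab.values[:, 1])
                    except (DegenerateTableError, ValueError):
                        t, p = np.nan, np.nan  # undefined: logged as NaN
                    row = {
                        "estimator": est, "band": band, "outcome": outcome,
                        "condition": cond,
                        "icc": icc_res.icc, "icc_lb": icc_res.ci_low,
                        "icc_ub": icc_res.ci_high,
                        "icc_category": icc_res.category,
                        "sem": cov_res.sem, "cov_percent": cov_res.cov_percent,
                        "cov_lb": cov_res.ci_low, "cov_ub": cov_res.ci_high,
                        "t_sessions": t, "p_sessions": p,
                    }
                    for j, sid in enumerate(tab.session_ids):
                        row[f"mean_{sid}"] = tab.values[:, j].mean()
                        row[f"sd_{sid}"] = tab.values[:, j].std(ddof=1)
                    rel_rows.append(row)
                if len(conditions) == 2:
                    a, b = (tables[c] for c in conditions)
                    cmp_row = {"estimator": est, "band": band,
                               "outcome": outcome,
                               "condition_a": conditions[0],
                               "condition_b": conditions[1]}
                    for statistic in ("icc", "cov"):
                        comp = bootstrap_reliability_compare(
                            a, b, statistic=statistic,
                            k_cycles=config.k_cycles,
                            seed=_child_seed(config.seed, idx),
                        )
                        idx += 1
                        cmp_row[f"es_{statistic}"] = comp.effect_size_d
                        cmp_row[f"degenerate_cycles_{statistic}"] = comp.n_degenerate
                        if comp.n_degenerate:
                            logger.warning(
                                "%s/%s/%s %s bootstrap: %d degenerate cycles",
                                est, band, outcome, statistic, comp.n_degenerate,
                            )
                    cmp_rows.append(cmp_row)
                    # 2x2 ANOVA: condition x session, fully within subject
                    n = tables[conditions[0]].n
                    if n < 3:
                        logger.warning(
                            "%s/%s/%s: ANOVA skipped (needs >= 3 participants, "
                            "have %d)", est, band, outcome, n)
                        continue
                    y = np.empty((n, 2, 2))
                    for a_idx, cond in enumerate(conditions):
                        y[:, a_idx, :] = tables[cond].values[:, :2]
                    res = rm_anova_2x2(y)
                    for eff, stats_ in res.effects.items():
                        anova_rows.append({
                            "estimator": est, "band": band, "outcome": outcome,
                            "effect": eff, "F": stats_.F, "p": stats_.p,
                            "df1": stats_.df1, "df2": stats_.df2,
                        })
    return {
        "reliability": pd.DataFrame(rel_rows),
        "comparisons": pd.DataFrame(cmp_rows),
        "anova": pd.DataFrame(anova_rows),
    }


# ---------------------------------------------------------------------------
# full run


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    recordings: Sequence[Recording] | None = None,
) -> dict[str, Path]:
    """Run every stage and write result CSVs plus a JSON run manifest.

    If no recordings are given they are simulated from ``config.design``
    and ``config.coupling`` (study defaults fill any gaps).  Outputs:
    outcomes.csv, reliability.csv, comparisons.csv, anova.csv,
    manifest.json.  Reruns with the same config and seed produce
    byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.snapshot(), "version": __version__,
                      "stages": {}}
    t0 = time.perf_counter()

    if recordings is None:
        design = config.design or StudyDesign(seed=config.seed)
        coupling = config.coupling or default_coupling(
            config.bands, n_channels=design.n_channels)
        logger.info("simulate: %d x %d x %d study", design.n_participants,
                    design.sessions, len(design.conditions))
        recordings = generate_study(design, coupling, seed=config.seed)
        manifest["stages"]["simulate"] = {
            "n_recordings": len(recordings),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    t1 = time.perf_counter()
    outcomes = compute_outcomes(recordings, config)
    manifest["stages"]["outcomes"] = {
        "n_rows": int(len(outcomes)),
        "seconds": round(time.perf_counter() - t1, 3),
    }

    t2 = time.perf_counter()
    tables = reliability_analysis(outcomes, config)
    manifest["stages"]["reliability"] = {
        "n_rows": int(len(tables["reliability"])),
        "seconds": round(time.perf_counter() - t2, 3),
    }

    paths: dict[str, Path] = {}
    for name, df in {"outcomes": outcomes, **tables}.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["stages"].setdefault("digests", {})[name] = digest
        paths[name] = path
    manifest["wall_clock_s"] = round(time.perf_counter() - t0, 3)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = manifest_path
    logger.info("pipeline finished in %.1f s", manifest["wall_clock_s"])
    return paths
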
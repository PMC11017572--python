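"""End-to-end experiments.

Three orchestrated analyses mirror the study design:

- :func:`run_congruence_survey` — all-pairs ANI over a set of annotated
  assemblies, nearest-neighbor selection, CDS clustering and congruence
  statistics per pair, with a pair-count-weighted trend of the incongruent
  fraction versus ANI.
- :func:`run_coverage_experiment` — binomial fit of spurious-pseudogene
  counts versus coverage/quality plus the two derived predictions (density
  at the 50-fold reporting point; coverage needed for one pseudogene
  difference per Mbp).
- :func:`run_filter_screen` — the nearest-neighbor binomial anomaly filter
  over a table of assembly statistics.

Every runner returns a tidy table plus a machine-readable manifest (inputs,
thresholds, seeds) sufficient to reproduce the outputs; stages log one line
with input/output row counts so filter attrition is auditable.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pseudocheck.annotation_io import AssemblyAnnotation
from pseudocheck.coverage_model import (
    ANI_GATE,
    BinomialFit,
    binomial_filter,
    coverage_for_density,
    fit_binomial,
    predict_density,
)
from pseudocheck.pair_comparison import (
    PAIR_CAUSES,
    ani,
    congruence_summary,
    match_cds,
    nearest_neighbor,
)
from pseudocheck.synthetic_data import observations_from_table

logger = logging.getLogger(__name__)

#: defaults mirrored across the pipeline
DEFAULT_MIN_SIMILARITY = 0.90
DEFAULT_REPORT_COVERAGE = 50.0
DEFAULT_TARGET_DENSITY = 1.0


def ani_matrix(
    assemblies: Sequence[AssemblyAnnotation], fragment_len: int = 1000
) -> pd.DataFrame:
    """Symmetric all-pairs ANI matrix (percent; NaN when undefined)."""
    ids = [a.assembly_id for a in assemblies]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(assemblies):
        mat.iloc[i, i] = 100.0
        for j in range(i + 1, len(assemblies)):
            res = ani(a, assemblies[j], fragment_len=fragment_len)
            value = np.nan if res.ani is None else res.ani
            mat.iloc[i, j] = value
            mat.iloc[j, i] = value
    return mat


def weighted_moving_median(
    x: Sequence[float], y: Sequence[float], w: Sequence[float], window: int = 5
) -> pd.DataFrame:
    """Weighted moving median of ``y`` against ``x``.

    For each point, the ``window`` nearest points by ``x`` contribute; the
    weighted median is the smallest y whose cumulative weight reaches half
    the total.  A robust stand-in for spline smoothing of the trend curves.
    """
    order = np.argsort(x)
    xs, ys, ws = (np.asarray(v, dtype=float)[order] for v in (x, y, w))
    out = []
    for i in range(len(xs)):
        lo = max(0, i - window // 2)
        hi = min(len(xs), lo + window)
        lo = max(0, hi - window)
        yy, ww = ys[lo:hi], ws[lo:hi]
        sub = np.argsort(yy)
        cum = np.cumsum(ww[sub])
        med = yy[sub][np.searchsorted(cum, cum[-1] / 2.0)]
        out.append({"x": xs[i], "median_y": med, "weight": ws[i]})
    return pd.DataFrame(out)


def run_congruence_survey(
    assemblies: Sequence[AssemblyAnnotation],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    fragment_len: int = 1000,
    trend_window: int = 5,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict]:
    """Congruence statistics for each assembly against its ANI-nearest
    neighbor.

    Returns (per-pair table, per-cause weighted trend tables, manifest).
    The per-pair table has one row per assembly with a defined neighbor.
    """
    if len(assemblies) < 2:
        raise ValueError("need at least 2 assemblies")
    with_seqs = [a.with_sequences() if a.contigs else a for a in assemblies]
    mat = ani_matrix(with_seqs, fragment_len=fragment_len)
    neighbors = nearest_neighbor(mat)
    by_id = {a.assembly_id: a for a in with_seqs}
    rows = []
    for aid in sorted(neighbors):
        partner, ani_value = neighbors[aid]
        clusters = match_cds(
            by_id[aid].features,
            by_id[partner].features,
            min_similarity=min_similarity,
            assembly_ids=(aid, partner),
        )
        summary = congruence_summary(clusters)
        row = {"assembly_id": aid, "neighbor_id": partner, "ani": ani_value}
        for cause in PAIR_CAUSES:
            row[f"n_congruent_{cause}"] = summary.n_congruent[cause]
            row[f"n_incongruent_{cause}"] = summary.n_incongruent[cause]
            row[f"fraction_incongruent_{cause}"] = summary.fraction_incongruent[cause]
            row[f"weight_{cause}"] = summary.weight[cause]
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info(
        "congruence survey: %d assemblies in, %d neighbor pairs out",
        len(assemblies),
        len(table),
    )
    trends = {}
    for cause in PAIR_CAUSES:
        sub = table.dropna(subset=[f"fraction_incongruent_{cause}"])
        sub = sub[sub[f"weight_{cause}"] > 0]
        if len(sub) >= 2:
            trends[cause] = weighted_moving_median(
                sub["ani"],
                sub[f"fraction_incongruent_{cause}"],
                sub[f"weight_{cause}"],
                window=trend_window,
            )
    manifest = {
        "analysis": "congruence_survey",
        "n_assemblies": len(assemblies),
        "min_similarity": min_similarity,
        "fragment_len": fragment_len,
        "trend_window": trend_window,
    }
    return table, trends, manifest


def run_coverage_experiment(
    observation_table: pd.DataFrame,
    genome_length: int | None = None,
    report_coverage: float = DEFAULT_REPORT_COVERAGE,
    report_quality: float = 35.0,
    target_density: float = DEFAULT_TARGET_DENSITY,
) -> tuple[dict[str, BinomialFit], pd.DataFrame, dict]:
    """Fit the binomial model per cause and derive the two predictions.

    ``observation_table`` is the tidy table from
    :func:`pseudocheck.synthetic_data.simulate_experiment` (columns cause,
    coverage, quality, k, n, genome_length).  Boundary fits are carried into
    the report with no predictions.
    """
    fits: dict[str, BinomialFit] = {}
    rows = []
    causes = sorted(observation_table["cause"].unique())
    for cause in causes:
        obs = observations_from_table(observation_table, cause)
        glen = genome_length
        if glen is None:
            glen = int(observation_table[observation_table["cause"] == cause]["genome_length"].iloc[0])
        n_cds = obs[0].n
        fit = fit_binomial(obs)
        fits[cause] = fit
        row = {
            "cause": cause,
            "n_obs": fit.n_obs,
            "boundary": fit.boundary,
            "separation": fit.separation,
            "beta0": fit.beta0,
            "beta_cov": fit.beta_cov,
            "beta_q": fit.beta_q,
        }
        if fit.boundary:
            row["density_at_report_coverage"] = None
            row["coverage_for_target_density"] = None
        else:
            row["density_at_report_coverage"] = predict_density(
                fit, report_coverage, report_quality, n_cds, glen
            )
            if fit.beta_cov < 0:
                sol = coverage_for_density(
                    fit, target_density, report_quality, n_cds, glen
                )
                row["coverage_for_target_density"] = sol.coverage
                row["coverage_solution_status"] = sol.status
            else:
                row["coverage_for_target_density"] = None
        rows.append(row)
        logger.info("coverage experiment: cause=%s n_obs=%d boundary=%s", cause, fit.n_obs, fit.boundary)
    report = pd.DataFrame(rows)
    manifest = {
        "analysis": "coverage_experiment",
        "report_coverage": report_coverage,
        "report_quality": report_quality,
        "target_density": target_density,
        "causes": causes,
    }
    return fits, report, manifest


def run_filter_screen(
    stats: pd.DataFrame,
    neighbors: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Apply the nearest-neighbor binomial anomaly filter.

    ``stats`` columns: assembly_id, n_stops, n_cds.  ``neighbors`` columns:
    assembly_id, neighbor_id, ani.  Assemblies without a >= 99.9%-ANI
    neighbor are reported not-evaluated.  The summary gives the rejected
    fraction among evaluated assemblies.
    """
    required = {"assembly_id", "n_stops", "n_cds"}
    if not required <= set(stats.columns):
        raise ValueError(f"stats table needs columns {sorted(required)}")
    if not {"assembly_id", "neighbor_id", "ani"} <= set(neighbors.columns):
        raise ValueError("neighbor table needs columns assembly_id, neighbor_id, ani")
    stats_by_id = stats.set_index("assembly_id")
    rows = []
    for rec in neighbors.itertuples():
        if rec.assembly_id not in stats_by_id.index or rec.neighbor_id not in stats_by_id.index:
            continue
        own = stats_by_id.loc[rec.assembly_id]
        nb = stats_by_id.loc[rec.neighbor_id]
        verdict = binomial_filter(
            n_stops=int(own.n_stops),
            n_cds=int(own.n_cds),
            neighbor_stops=int(nb.n_stops),
            neighbor_n_cds=int(nb.n_cds),
            neighbor_ani=float(rec.ani),
        )
        rows.append(
            {
                "assembly_id": rec.assembly_id,
                "neighbor_id": rec.neighbor_id,
                "neighbor_ani": verdict.neighbor_ani,
                "n_stops": verdict.n_stops,
                "n_cds": verdict.n_cds,
                "neighbor_rate": verdict.neighbor_rate,
                "threshold": verdict.threshold,
                "evaluated": verdict.evaluated,
                "reject": verdict.reject,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "assembly_id",
            "neighbor_id",
            "neighbor_ani",
            "n_stops",
            "n_cds",
            "neighbor_rate",
            "threshold",
            "evaluated",
            "reject",
        ],
    )
    n_eval = int(table["evaluated"].sum()) if len(table) else 0
    n_rej = int(table["reject"].sum()) if len(table) else 0
    summary = {
        "analysis": "filter_screen",
        "ani_gate": ANI_GATE,
        "n_input": len(neighbors),
        "n_evaluated": n_eval,
        "n_rejected": n_rej,
        "fraction_rejected": (n_rej / n_eval) if n_eval else None,
    }
    logger.info(
        "filter screen: %d in, %d evaluated, %d rejected", len(neighbors), n_eval, n_rej
    )
    return table, summary


def assembly_stats_table(assemblies: Sequence[AssemblyAnnotation]) -> pd.DataFrame:
    """Per-assembly internal-stop counts feeding :func:`run_filter_screen`."""
    from pseudocheck.annotation_io import pseudogene_density

    rows = []
    for asm in assemblies:
        dens = pseudogene_density(asm)
        rows.append(
            {
                "assembly_id": asm.assembly_id,
                "n_stops": dens.n_internal_stop,
                "n_frameshift": dens.n_frameshift,
                "n_cds": dens.n_cds_total,
                "genome_length": asm.genome_length,
            }
        )
    return pd.DataFrame(rows)


def neighbor_table(ani_mat: pd.DataFrame) -> pd.DataFrame:
    """Nearest-neighbor table (assembly_id, neighbor_id, ani) from an ANI
    matrix."""
    nn = nearest_neighbor(ani_mat)
    return pd.DataFrame(
        [{"assembly_id": a, "neighbor_id": p, "ani": v} for a, (p, v) in sorted(nn.items())]
    )
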
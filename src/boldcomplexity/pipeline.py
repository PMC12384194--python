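"""End-to-end workflows: per-subject complexity maps and cohort inference.

The subject workflow is the fixed chain
discard -> motion regression -> band-pass -> intensity mask -> three
voxel-wise maps -> whole-brain means; the mask is computed on the
post-discard, *unfiltered* intensities.  The cohort workflow produces
descriptives with group t-tests, per-group 21-pair correlation matrices
with BH-FDR flags, Fisher r-to-z comparisons of the PIQ-entropy
correlations, and the two moderation models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .maps import ComplexityMap, map_report, voxelwise_metric, whole_brain_mean
from .preprocess import (
    BrainMask,
    Volume4D,
    bandpass,
    compute_mask,
    discard_initial_volumes,
    regress_nuisance,
)
from .stats import (
    ANALYSIS_VARS,
    GROUPS,
    CohortTable,
    correlation_matrix,
    fdr_bh,
    fisher_compare,
    independent_ttest,
    interaction_model,
)

__all__ = ["SubjectResult", "run_subject", "run_cohort"]


@dataclass(frozen=True)
class SubjectResult:
    """Maps plus whole-brain summaries for one preprocessed subject."""

    maps: dict  # metric tag -> ComplexityMap
    summaries: dict  # metric tag -> WholeBrainSummary
    mask: BrainMask
    config: RunConfig

    def summary_dict(self) -> dict:
        out = {"n_mask_voxels": self.mask.n_voxels, "metrics": {}}
        for tag, s in self.summaries.items():
            out["metrics"][tag] = {
                "mean": s.mean, "sd": s.sd, "n_voxels": s.n_voxels,
                "n_degenerate": s.n_degenerate,
            }
        out["reports"] = {tag: map_report(m) for tag, m in self.maps.items()}
        return out


def preprocess_subject(
    vol: Volume4D, motion: np.ndarray, config: RunConfig | None = None
) -> tuple[Volume4D, BrainMask]:
    """Run the temporal preprocessing chain and derive the brain mask."""
    config = config or RunConfig()
    vol = discard_initial_volumes(vol, config.n_discard)
    if motion.shape[0] == vol.n_volumes + config.n_discard:
        motion = motion[config.n_discard:]
    vol = regress_nuisance(vol, motion)
    mask = compute_mask(vol, config.mask_fraction)  # pre-filter intensities
    vol = bandpass(vol, config.low_hz, config.high_hz)
    return vol, mask


def run_subject(
    vol: Volume4D, motion: np.ndarray, config: RunConfig | None = None
) -> SubjectResult:
    """Full per-subject workflow: preprocessing plus the three maps."""
    config = config or RunConfig()
    clean, mask = preprocess_subject(vol, motion, config)
    maps: dict[str, ComplexityMap] = {}
    summaries = {}
    for tag in ("hurst", "fapen", "fsampen"):
        params = config.hurst_params() if tag == "hurst" else config.entropy_params()
        maps[tag] = voxelwise_metric(clean, mask, tag, params)
        summaries[tag] = whole_brain_mean(maps[tag])
    return SubjectResult(maps, summaries, mask, config)


def _corr_section(cohort: CohortTable, group: str, config: RunConfig) -> dict:
    results = correlation_matrix(cohort, group, config.conf)
    reject, p_adj = fdr_bh([c.p for c in results], config.q)
    out = []
    for c, rej, pa in zip(results, reject, p_adj):
        d = c.asdict()
        d["p_fdr"] = float(pa)
        d["significant_fdr"] = bool(rej)
        out.append(d)
    return {"group": group, "n": len(cohort.group(group)), "correlations": out}


def run_cohort(cohort: CohortTable, config: RunConfig | None = None) -> dict:
    """Cohort inference report as a JSON-ready dictionary."""
    config = config or RunConfig()
    cohort.require_inferential()
    sizes = cohort.group_sizes()

    descriptives = {}
    for var in ANALYSIS_VARS:
        a = cohort.group("ASD")[var]
        b = cohort.group("Control")[var]
        descriptives[var] = independent_ttest(a, b).asdict()

    correlations = {g: _corr_section(cohort, g, config) for g in GROUPS}

    comparisons = {}
    for ent in ("fapen", "fsampen"):
        per_group = {}
        for g in GROUPS:
            sub = cohort.group(g)
            row = next(
                c for c in correlation_matrix(cohort, g, config.conf)
                if {c.var_x, c.var_y} == {"piq", ent}
            )
            per_group[g] = row.asdict()
        fc = fisher_compare(
            per_group["ASD"]["r"], sizes["ASD"],
            per_group["Control"]["r"], sizes["Control"],
        )
        comparisons[f"piq_{ent}"] = {"groups": per_group, "fisher": fc.asdict()}

    models = {
        ent: interaction_model(cohort, ent, config.conf).asdict()
        for ent in ("fapen", "fsampen")
    }

    return {
        "group_sizes": sizes,
        "descriptives": descriptives,
        "correlations": correlations,
        "piq_entropy_comparisons": comparisons,
        "interaction_models": models,
        "config": config.asdict(),
    }


def format_cohort_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_cohort` output (same numbers)."""
    lines = []
    sizes = report["group_sizes"]
    lines.append(f"Cohort: ASD n={sizes['ASD']}, Control n={sizes['Control']}")
    lines.append("")
    lines.append("Descriptives (mean [SD]) with pooled t-tests")
    for var, d in report["descriptives"].items():
        lines.append(
            f"  {var:8s} ASD {d['mean_asd']:8.3f} [{d['sd_asd']:.3f}]  "
            f"Control {d['mean_control']:8.3f} [{d['sd_control']:.3f}]  "
            f"t({d['df']})={d['t']:.2f}, p={d['p']:.3f}"
        )
    for g, sec in report["correlations"].items():
        lines.append("")
        lines.append(f"Correlations within {g} (n={sec['n']}, BH-FDR)")
        for c in sec["correlations"]:
            star = " *" if c["significant_fdr"] else ""
            lines.append(
                f"  {c['pair']:18s} r={c['r']:+.3f} "
                f"CI[{c['ci_low']:+.3f}, {c['ci_high']:+.3f}] "
                f"p={c['p']:.4f} p_fdr={c['p_fdr']:.4f}{star}"
            )
    lines.append("")
    lines.append("PIQ-entropy group comparisons (Fisher r-to-z)")
    for pair, d in report["piq_entropy_comparisons"].items():
        f = d["fisher"]
        lines.append(
            f"  {pair:12s} r_ASD={f['r1']:+.3f} (n={f['n1']}) "
            f"r_Control={f['r2']:+.3f} (n={f['n2']}) "
            f"z={f['z']:.2f} p={f['p']:.4f}"
        )
    lines.append("")
    lines.append("Moderation models predicting PIQ (group coded ASD=1, Control=2)")
    for ent, m in report["interaction_models"].items():
        lines.append(f"  Model: {ent} (R^2={m['r_squared']:.3f}, n={m['n']})")
        for term, t in m["terms"].items():
            beta = "      " if t["beta"] is None else f"{t['beta']:+.3f}"
            lines.append(
                f"    {term:12s} B={t['B']:9.2f} SE={t['SE']:8.2f} "
                f"beta={beta} t={t['t']:+.2f} p={t['p']:.4f} "
                f"CI[{t['ci_low']:.2f}, {t['ci_high']:.2f}]"
            )
        sl = m["group_slopes"]
        lines.append(
            f"    implied slopes: ASD {sl['ASD']:.2f}, Control {sl['Control']:.2f}"
        )
    return "\n".join(lines)
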
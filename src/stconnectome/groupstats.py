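"""Group-level inference on spatiotemporal connectome measures.

Three procedures:

* :func:`permutation_test` — two-tailed subject-permutation test on a
  group-level metric (SD or STD) at the global or a functional-system scale.
  The unit of exchangeability is the subject: each permutation reassigns
  whole subjects (their entire CC sets) between groups, preserving group
  sizes, and recomputes the pooled metric difference.  The p-value uses the
  +1-smoothed estimator p = (1 + #{|d_perm| >= |d_obs|}) / (n_valid + 1),
  so p >= 1/(n_valid + 1) always.  Permutations on which a pooled metric is
  undefined (empty sub-pool, no region in two components) are dropped and
  counted.
* :func:`fdr_adjust` — Benjamini-Hochberg step-up q-values across the eight
  per-system tests, applied separately per metric family.
* :func:`ancova` — OLS fit of a per-subject CC characteristic (count, mean
  length, mean height) on group + age + group:age with effect-coded group
  and mean-centered age, Type-III F tests (df_den = n - 4).

:func:`run_study` chains the full pipeline from files on disk to a report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from ._core import SYSTEMS, InsufficientDataError, ValidationError
from .diversity import (
    CCPool,
    SCALES,
    spatiotemporal_diversity,
    system_diversity,
)


@dataclass(frozen=True)
class PermutationResult:
    scale: str
    metric: str
    observed_a: float
    observed_b: float
    observed_diff: float
    p_two_tailed: float
    n_perm: int
    n_valid_perms: int
    seed: int


@dataclass(frozen=True)
class AncovaResult:
    response: str
    terms: dict  # term -> {"F": float, "p": float, "df_num": int}
    df_den: int
    n_used: int
    excluded: list


def _metric_value(pool: CCPool, metric: str, sd_variant: str, std_variant: str) -> float:
    if metric == "SD":
        return system_diversity(pool, sd_variant).value
    if metric == "STD":
        return spatiotemporal_diversity(pool, std_variant).value
    raise ValidationError(f"unknown metric {metric!r}")


def permutation_test(
    pool: CCPool,
    groups: dict[str, str],
    metric: str = "SD",
    scale: str = "global",
    n_perm: int = 1000,
    seed: int = 0,
    attribution_frac: float = 0.20,
    sd_variant: str = "mean_cc",
    std_variant: str = "region_pairs",
    method: str = "permutation",
) -> PermutationResult:
    """Two-tailed subject-permutation test of metric(A) - metric(B).

    Parameters
    ----------
    pool
        All subjects' CCs concatenated (both groups), with subject ids.
    groups
        Mapping subject_id -> "A" | "B"; subjects with zero CCs still count
        as exchangeable units.
    metric, scale
        "SD" or "STD"; "global" or one of the eight system names (system
        scales restrict the pool by the 20% attribution rule first).
    method
        "permutation" (default, label shuffles without replacement) or
        "bootstrap" (groups resampled from the roster with replacement).
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    if method not in ("permutation", "bootstrap"):
        raise ValidationError(f"unknown method {method!r}")
    work = pool if scale == "global" else pool.restrict_to_system(scale, attribution_frac)

    roster = sorted(groups)
    grp = np.array([groups[s] for s in roster], dtype=object)
    bad = set(np.unique(grp)) - {"A", "B"}
    if bad or "A" not in grp or "B" not in grp:
        raise ValidationError("groups must contain both labels 'A' and 'B' only")
    n_subj = len(roster)
    n_a = int((grp == "A").sum())
    sid_to_row = {s: k for k, s in enumerate(roster)}
    cc_rows = np.array([sid_to_row[s] for s in work.subjects], dtype=np.int64)

    # Per-subject sufficient statistics: SD needs (sum of entropies, count);
    # STD needs per-region unit-embedding sums and CC counts.
    ent_sum = np.bincount(cc_rows, weights=work.entropies, minlength=n_subj)
    cc_cnt = np.bincount(cc_rows, minlength=n_subj).astype(float)
    n_regions = work.parc.n_regions
    s_arr = np.zeros((n_subj, n_regions * 8))
    c_arr = np.zeros((n_subj, n_regions))
    if work.n_cc:
        inc = work.incidence.tocoo()
        # region-by-cc incidence scattered into per-subject accumulators
        np.add.at(
            s_arr.reshape(n_subj, n_regions, 8),
            (cc_rows[inc.col], inc.row),
            work.unit_emb[inc.col],
        )
        np.add.at(c_arr, (cc_rows[inc.col], inc.row), 1.0)

    def metric_from_mask(mask: np.ndarray) -> float:
        """Pooled metric for the subjects selected by a boolean row mask."""
        if metric == "SD":
            total = cc_cnt @ mask
            if total == 0:
                raise InsufficientDataError("empty pool in permutation")
            if sd_variant != "mean_cc":
                sub = work.subset(np.isin(cc_rows, np.flatnonzero(mask)))
                return _metric_value(sub, metric, sd_variant, std_variant)
            return float((ent_sum @ mask) / total)
        if std_variant != "region_pairs":
            sub = work.subset(np.isin(cc_rows, np.flatnonzero(mask)))
            return _metric_value(sub, metric, sd_variant, std_variant)
        s = (mask @ s_arr).reshape(n_regions, 8)
        n = mask @ c_arr
        from .diversity import std_from_stats

        value, _ = std_from_stats(s, n)
        return value

    obs_mask_a = (grp == "A").astype(float)
    obs_mask_b = (grp == "B").astype(float)
    observed_a = metric_from_mask(obs_mask_a)  # raises if undefined
    observed_b = metric_from_mask(obs_mask_b)
    observed_diff = observed_a - observed_b

    rng = np.random.default_rng(seed)
    diffs = []
    n_invalid = 0
    for _ in range(n_perm):
        if method == "permutation":
            perm = rng.permutation(n_subj)
            rows_a, rows_b = perm[:n_a], perm[n_a:]
        else:
            rows_a = rng.integers(n_subj, size=n_a)
            rows_b = rng.integers(n_subj, size=n_subj - n_a)
        mask_a = np.bincount(rows_a, minlength=n_subj).astype(float)
        mask_b = np.bincount(rows_b, minlength=n_subj).astype(float)
        try:
            diffs.append(metric_from_mask(mask_a) - metric_from_mask(mask_b))
        except InsufficientDataError:
            n_invalid += 1
    diffs = np.asarray(diffs)
    n_valid = diffs.size
    if n_valid == 0:
        raise InsufficientDataError("all permutations had undefined metrics")
    p = (1.0 + np.sum(np.abs(diffs) >= np.abs(observed_diff))) / (n_valid + 1.0)
    return PermutationResult(
        scale=scale,
        metric=metric,
        observed_a=observed_a,
        observed_b=observed_b,
        observed_diff=observed_diff,
        p_two_tailed=float(p),
        n_perm=n_perm,
        n_valid_perms=int(n_valid),
        seed=seed,
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ancova(subjects: pd.DataFrame, response: str) -> AncovaResult:
    """Type-III ANCOVA of a per-subject response on group, age, group x age.

    ``subjects`` needs columns ``subject_id``, ``group`` (two levels),
    ``age``, and the response.  Group is effect-coded (sum contrasts) and
    age mean-centered so the Type-III tests are interpretable with the
    interaction present.  Subjects with an undefined (NaN) response are
    excluded and reported.
    """
    required = {"subject_id", "group", "age", response}
    missing = required - set(subjects.columns)
    if missing:
        raise ValidationError(f"subject table missing columns {sorted(missing)}")
    df = subjects.copy()
    excluded = df.loc[~np.isfinite(df[response].astype(float)), "subject_id"].tolist()
    df = df[np.isfinite(df[response].astype(float))].copy()
    counts = df.groupby("group").size()
    if len(counts) != 2 or counts.min() < 2:
        raise ValidationError("need two groups with >= 2 usable subjects each")
    df["age_c"] = df["age"] - df["age"].mean()
    df["_y"] = df[response].astype(float)
    if df["_y"].nunique() == 1:
        # degenerate response: no variance to attribute to any term
        terms = {
            t: {"F": 0.0, "p": 1.0, "df_num": 1} for t in ("group", "age", "group:age")
        }
        return AncovaResult(
            response=response,
            terms=terms,
            df_den=int(len(df) - 4),
            n_used=int(len(df)),
            excluded=excluded,
        )
    model = smf.ols("_y ~ C(group, Sum) * age_c", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValidationError("rank-deficient design")
    table = sm.stats.anova_lm(model, typ=3)
    name_map = {
        "C(group, Sum)": "group",
        "age_c": "age",
        "C(group, Sum):age_c": "group:age",
    }
    terms = {}
    for raw, nice in name_map.items():
        row = table.loc[raw]
        terms[nice] = {
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
            "df_num": int(row["df"]),
        }
    return AncovaResult(
        response=response,
        terms=terms,
        df_den=int(model.df_resid),
        n_used=int(len(df)),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Full-study orchestration


@dataclass(frozen=True)
class StudyReport:
    """Everything one study run produces, plus reproducibility metadata."""

    subjects: pd.DataFrame  # per-subject CC summaries
    metrics: pd.DataFrame  # group x scale x metric diversity values
    permutation: pd.DataFrame  # scale x metric tests with p and q
    ancova: pd.DataFrame  # term-level F tests for the three responses
    config_hash: str
    seed: int
    warnings: list


def run_study(config, write: bool = True) -> StudyReport:
    """Execute the whole chain on a study directory described by ``config``.

    Stages: read manifest/labels/structural matrix; point process per
    subject (skipped for binary raster inputs); multilayer graph and CC
    extraction; group pooling; SD/STD at the global and 8 system scales;
    permutation tests (2 metrics x 9 scales) with BH-FDR within each
    metric's 8 system tests; three ANCOVAs (n_cc, mean_length, mean_height).
    With ``write=True`` also writes ``metrics.csv``, ``permutation.csv``,
    ``ancova.csv`` and ``report.yaml`` (all deterministic for a fixed
    config + seed) under the output dir.
    """
    from . import io as stio
    from .diversity import scale_metrics
    from .pointprocess import ActivationRaster, zscore_threshold
    from .stgraph import build_graph, cc_summary, extract_components

    warnings: list[str] = []

    def _stage(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with the failing stage
            raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = _stage("io", stio.read_manifest, config.manifest)
    sc = _stage("io", stio.read_structural, config.structural)
    labels = _stage("io", stio.read_labels, config.labels, sc.n_regions)

    base = os.path.dirname(str(config.manifest))
    all_components = []
    subj_rows = []
    for rec in manifest.itertuples(index=False):
        data, _ = _stage("io", stio.read_matrix_tsv, os.path.join(base, rec.path))
        if config.input_kind == "raster":
            raster = ActivationRaster(active=data, threshold_used=float("nan"))
        else:
            raster = _stage("pointprocess", zscore_threshold, data, config.threshold)
            n_const = int(np.sum(data.std(axis=1) == 0))
            if n_const:
                warnings.append(
                    f"pointprocess/{rec.subject_id}: {n_const} zero-variance regions"
                )
        graph = _stage("stgraph", build_graph, raster, sc, config.sc_threshold)
        ccset = _stage(
            "stgraph", extract_components, graph, config.min_cc_size, rec.subject_id
        )
        if ccset.n_discarded:
            warnings.append(
                f"stgraph/{rec.subject_id}: discarded {ccset.n_discarded} "
                f"components below min_size={config.min_cc_size}"
            )
        all_components.extend(ccset.components)
        row = {"subject_id": rec.subject_id, "group": rec.group, "age": rec.age}
        row.update(cc_summary(ccset))
        subj_rows.append(row)
    subjects = pd.DataFrame(subj_rows)

    pool = CCPool(all_components, labels)
    groups = dict(zip(manifest["subject_id"], manifest["group"]))

    metric_rows = []
    for grp_label in ("A", "B"):
        sub = pool.subset(np.isin(pool.subjects, [s for s, g in groups.items() if g == grp_label]))
        for dv in _stage(
            "diversity",
            scale_metrics,
            sub,
            config.attribution_frac,
            config.sd_variant,
            config.std_variant,
        ):
            metric_rows.append(
                {
                    "group": grp_label,
                    "scale": dv.scale,
                    "metric": dv.metric,
                    "value": dv.value,
                    "n_cc_used": dv.n_cc_used,
                    "n_regions_used": dv.n_regions_used,
                }
            )
    metrics = pd.DataFrame(metric_rows)

    perm_rows = []
    rng = np.random.default_rng(config.seed)
    for metric in ("SD", "STD"):
        for scale in SCALES:
            test_seed = int(rng.integers(2**31 - 1))
            try:
                res = _stage(
                    "groupstats",
                    permutation_test,
                    pool,
                    groups,
                    metric,
                    scale,
                    config.n_perm,
                    test_seed,
                    config.attribution_frac,
                    config.sd_variant,
                    config.std_variant,
                )
            except InsufficientDataError as exc:
                warnings.append(f"groupstats/{metric}@{scale}: skipped ({exc})")
                continue
            if res.n_valid_perms < res.n_perm:
                warnings.append(
                    f"groupstats/{metric}@{scale}: dropped "
                    f"{res.n_perm - res.n_valid_perms} undefined permutations"
                )
            perm_rows.append(
                {
                    "scale": res.scale,
                    "metric": res.metric,
                    "value_a": res.observed_a,
                    "value_b": res.observed_b,
                    "diff": res.observed_diff,
                    "p": res.p_two_tailed,
                    "n_perm": res.n_perm,
                    "n_valid_perms": res.n_valid_perms,
                }
            )
    permutation = pd.DataFrame(perm_rows)
    permutation["q"] = np.nan
    for metric in ("SD", "STD"):
        sys_mask = (permutation["metric"] == metric) & (permutation["scale"] != "global")
        if sys_mask.any():
            permutation.loc[sys_mask, "q"] = fdr_adjust(permutation.loc[sys_mask, "p"])

    anc_rows = []
    for response in ("n_cc", "mean_length", "mean_height"):
        try:
            res = _stage("groupstats", ancova, subjects, response)
        except ValidationError as exc:
            warnings.append(f"groupstats/ancova[{response}]: skipped ({exc})")
            continue
        for excl in res.excluded:
            warnings.append(f"groupstats/ancova[{response}]: excluded subject {excl}")
        for term, vals in res.terms.items():
            anc_rows.append(
                {
                    "response": response,
                    "term": term,
                    "F": vals["F"],
                    "p": vals["p"],
                    "df_num": vals["df_num"],
                    "df_den": res.df_den,
                    "n_used": res.n_used,
                }
            )
    anc = pd.DataFrame(anc_rows)

    chash = stio.config_hash(config)
    report = StudyReport(
        subjects=subjects,
        metrics=metrics,
        permutation=permutation,
        ancova=anc,
        config_hash=chash,
        seed=config.seed,
        warnings=warnings,
    )
    if write:
        from pathlib import Path

        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        subjects.to_csv(out / "subjects.csv", index=False, float_format="%.10g")
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        permutation.to_csv(out / "permutation.csv", index=False, float_format="%.10g")
        anc.to_csv(out / "ancova.csv", index=False, float_format="%.10g")
        import yaml

        (out / "report.yaml").write_text(
            yaml.safe_dump(
                {
                    "config_hash": chash,
                    "seed": config.seed,
                    "n_subjects": int(len(subjects)),
                    "n_components_pooled": int(pool.n_cc),
                    "warnings": warnings,
                },
                sort_keys=True,
            )
        )
    return report
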
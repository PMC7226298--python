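"""End-to-end study orchestration.

``run_study`` takes a run configuration holding either a simulation spec
(design + ground truth) or paths to input tables, and carries the data
through enrichment extraction, QC, kinetic fitting and cohort statistics,
producing the study's result surfaces:

* table1 — covariate descriptives and group tests,
* table2 — HDL-cholesterol kinetics per group (t-test convention),
* table3 — protein half-lives per group (Yuen convention),
* table4 — percentage-bend correlations,
* table5 — Theil-Sen regressions (plus the regression figure data),
* figure1 — group mean +- SD cholesterol enrichment versus time,

together with per-peptide and per-protein fit tables, the QC rejection
log and a reproducibility manifest.  Protein FCRs in the association
surfaces are expressed per hour (the regression-figure convention);
half-lives are in hours and cholesterol kinetics in days.

No multiple-testing correction is applied anywhere; every p-value is a
single-contrast test at alpha = 0.05.  The output tables carry this note
in their metadata column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import isotopes, kinetics, robust, synthetic
from .constants import HOURS_PER_DAY
from .errors import ConfigurationError, MissingDataError

__all__ = ["StatsSettings", "RunConfig", "CohortResult", "run_study",
           "compare_groups", "association_analyses", "render_reports"]

_NOTE = "single-contrast p-values; no multiple-testing correction applied"


@dataclass
class StatsSettings:
    """Statistical conventions of the report surfaces."""

    trim: float = 0.2
    n_boot: int = 2000
    seed: int = 0
    #: which test backs each group-comparison table
    table_tests: dict[str, str] = field(
        default_factory=lambda: {"table2": "t_test", "table3": "yuen"}
    )


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``design`` (simulate) or ``inputs`` (paths to CSV
    tables: subjects, peptides, cholesterol, acetone_calibration,
    acetone_samples) must be provided.
    """

    design: synthetic.StudyDesign | None = None
    truth: synthetic.GroundTruth | None = None
    inputs: dict[str, Any] | None = None
    qc: kinetics.QCConfig = field(default_factory=kinetics.QCConfig)
    stats: StatsSettings = field(default_factory=StatsSettings)
    study_duration_d: float = 7.0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.design is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of a simulation design or input paths is required"
            )

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortResult:
    """Every result surface of one run."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    figure1: pd.DataFrame
    figure2: pd.DataFrame
    figure3: pd.DataFrame
    protein_kinetics: pd.DataFrame
    peptide_fits: pd.DataFrame
    cholesterol_kinetics: pd.DataFrame
    rejections: pd.DataFrame
    manifest: dict[str, Any]


# ---------------------------------------------------------------------------
# ingestion


_INPUT_TABLES = ("subjects", "peptides", "cholesterol", "acetone_calibration", "acetone_samples")


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.design is not None:
        return synthetic.generate_study(config.design, config.truth)
    tables: dict[str, pd.DataFrame] = {}
    for name in _INPUT_TABLES:
        path = config.inputs.get(name)
        if path is None:
            continue
        if isinstance(path, pd.DataFrame):
            tables[name] = path
            continue
        try:
            tables[name] = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surface file context
            raise ConfigurationError(f"cannot parse {name} table at {path}: {exc}") from exc
    if "subjects" not in tables or tables["subjects"].empty:
        raise ConfigurationError("empty cohort: no subjects table")
    return tables


def _subject_mpe(tables: Mapping[str, pd.DataFrame]) -> dict[str, float]:
    """Per-subject body-water MPE (fraction), preferring the acetone route."""
    if "acetone_calibration" in tables and "acetone_samples" in tables:
        cal = isotopes.body_water_enrichment(
            tables["acetone_calibration"], tables["acetone_samples"]
        )
        ids = tables["acetone_samples"]["subject_id"].tolist()
        return {sid: float(m) for sid, m in zip(ids, cal.sample_mpe)}
    if "body_water" in tables:
        out = {}
        for sid, grp in tables["body_water"].groupby("subject_id"):
            series = pd.Series(grp["mpe"].to_numpy(), index=grp["time_h"].to_numpy())
            out[str(sid)] = synthetic.plateau_mpe(series)
        return out
    raise ConfigurationError("no body-water enrichment source (acetone tables or body_water)")


# ---------------------------------------------------------------------------
# peptide processing


def _peptide_curves(
    peptides: pd.DataFrame, qc: kinetics.QCConfig
) -> tuple[list[kinetics.PeptideRecord], dict, pd.DataFrame, dict]:
    """Build per-peptide enrichment curves and QC records.

    Returns (records, curves keyed by (subject, accession, peptide),
    duplicate-flag log, baseline A0 per key).
    """
    mz_cols = sorted(
        (c for c in peptides.columns if c.startswith("i_m")),
        key=lambda c: int(c[3:]),
    )
    if not mz_cols:
        raise ConfigurationError("peptide table lacks isotopomer intensity columns i_m0..")
    accession_count = peptides.groupby("peptide")["accession"].nunique()

    records, curves, baselines, flag_rows = [], {}, {}, []
    for key, grp in peptides.groupby(["subject_id", "accession", "peptide"], sort=True):
        sid, acc, pep = key
        inten = grp[mz_cols].to_numpy(dtype=float)
        a0 = inten[:, 0] / inten.sum(axis=1)
        grp = grp.assign(_a0=a0)
        base_rows = grp[grp["time_h"] == 0.0]
        if base_rows.empty:
            continue
        base_a0 = float(base_rows["_a0"].mean())
        times, values = [], []
        for t_h, sub in grp.groupby("time_h"):
            e_vals = base_a0 - sub["_a0"].to_numpy()
            e_mean, flagged = isotopes.average_duplicates(e_vals[:2])
            if flagged:
                flag_rows.append(
                    {"subject": sid, "accession": acc, "peptide": pep,
                     "time_h": float(t_h), "issue": "duplicate injections differ > 2%"}
                )
            times.append(float(t_h) / HOURS_PER_DAY)
            values.append(e_mean)
        records.append(
            kinetics.PeptideRecord(
                subject=str(sid),
                accession=str(acc),
                peptide=str(pep),
                id_score=float(grp["id_score"].median()),
                intensity=float(np.exp(np.log(grp["total_intensity"]).mean())),
                n_timepoints=len(times),
                unique=accession_count[pep] == 1,
                charge=int(grp["charge"].iloc[0]) if "charge" in grp else 2,
            )
        )
        curves[key] = kinetics.LabelingCurve(
            analyte=f"{acc}:{pep}", subject=str(sid),
            time_d=np.array(times), enrichment=np.array(values),
        )
        baselines[key] = base_a0
    flags = pd.DataFrame(flag_rows, columns=["subject", "accession", "peptide", "time_h", "issue"])
    return records, curves, flags, baselines


def _protein_kinetics(
    tables: Mapping[str, pd.DataFrame],
    subjects: pd.DataFrame,
    mpe_by_subject: Mapping[str, float],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Peptide fits, protein-level kinetics and the rejection log."""
    records, curves, dup_flags, baselines = _peptide_curves(tables["peptides"], config.qc)
    retained, rejections = kinetics.filter_peptides(records, config.qc)
    retained_keys = {(r.subject, r.accession, r.peptide) for r in retained}

    pep_rows = []
    fits_by_key = {}
    for key, curve in curves.items():
        if tuple(map(str, key)) not in retained_keys:
            continue
        fit = kinetics.fit_exponential_rise(curve, config.qc)
        fits_by_key[key] = fit
        pep_rows.append(
            {
                "subject_id": key[0], "accession": key[1], "peptide": key[2],
                "ok": fit.ok, "excluded": fit.excluded, "k_per_day": fit.k,
                "e_as": fit.e_as, "r_squared": fit.r_squared,
                "half_life_h": fit.half_life_h, "outliers_removed": fit.outliers_removed,
                "reason": fit.reason,
            }
        )
    peptide_fits = pd.DataFrame(pep_rows)

    name_by_acc = {}
    if "protein" in tables["peptides"].columns:
        name_by_acc = (
            tables["peptides"].groupby("accession")["protein"].first().to_dict()
        )
    group_by_subject = subjects.set_index("subject_id")["group"].to_dict()

    prot_rows = []
    by_protein: dict[tuple, list] = {}
    for key, fit in fits_by_key.items():
        by_protein.setdefault((key[0], key[1]), []).append(key)
    for (sid, acc), keys in sorted(by_protein.items()):
        fits = [fits_by_key[k] for k in keys]
        curvs = [curves[k] for k in keys]
        agg_curve, agg_fit = kinetics.aggregate_protein_curve(fits, curvs, config.qc)
        method = "unquantified"
        if agg_fit.ok:
            method = kinetics.select_method(agg_curve, agg_fit, config.study_duration_d)
            if method == "precursor_product":
                pp_ks = []
                for k in keys:
                    seq = k[2]
                    pp = kinetics.fit_precursor_product(
                        curves[k],
                        isotopes.exchangeable_hydrogens(seq),
                        mpe_by_subject[str(sid)],
                        baseline_a0=baselines[k],
                    )
                    if pp.ok:
                        pp_ks.append(pp.k)
                if pp_ks:
                    k_mean = float(np.mean(pp_ks))
                    agg_fit = kinetics.KineticFit(
                        analyte=str(acc), subject=str(sid), ok=True, k=k_mean,
                        half_life_h=kinetics.half_life(k_mean),
                        residence_time_d=kinetics.residence_time(k_mean),
                        method="precursor_product", n_points_used=agg_fit.n_points_used,
                        n_peptides=len(pp_ks),
                    )
                else:
                    method = "unquantified"
                    agg_fit = kinetics.KineticFit.failure(
                        str(acc), str(sid), "no positive labeling slope", "precursor_product"
                    )
        prot_rows.append(
            {
                "subject_id": sid, "group": group_by_subject.get(sid, "?"),
                "accession": acc, "protein": name_by_acc.get(acc, acc),
                "method": method, "ok": agg_fit.ok,
                "k_per_day": agg_fit.k, "fcr_per_h": agg_fit.k / HOURS_PER_DAY,
                "e_as": agg_fit.e_as, "r_squared": agg_fit.r_squared,
                "half_life_h": agg_fit.half_life_h,
                "residence_time_d": agg_fit.residence_time_d,
                "n_peptides": agg_fit.n_peptides, "reason": agg_fit.reason,
            }
        )
    protein_kinetics = pd.DataFrame(prot_rows)
    return peptide_fits, protein_kinetics, rejections


def _cholesterol_kinetics(
    tables: Mapping[str, pd.DataFrame], subjects: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    rows = []
    relaxed = dataclasses.replace(config.qc, min_r_squared=1e-12)
    chol = tables["cholesterol"]
    for sid, grp in chol.groupby("subject_id"):
        times, values = [], []
        for t_h, sub in grp.groupby("time_h"):
            e_mean, _ = isotopes.average_duplicates(sub["enrichment"].to_numpy()[:2])
            times.append(float(t_h) / HOURS_PER_DAY)
            values.append(e_mean)
        curve = kinetics.LabelingCurve("HDL-C", str(sid), np.array(times), np.array(values))
        fit = kinetics.fit_exponential_rise(curve, relaxed, e_as_max=0.5)
        row = {
            "subject_id": sid,
            "group": subjects.set_index("subject_id")["group"].get(sid, "?"),
            "ok": fit.ok, "fcr_per_day": fit.k, "e_as": fit.e_as,
            "r_squared": fit.r_squared, "half_life_h": fit.half_life_h,
            "residence_time_d": fit.residence_time_d,
            "pool_size_mg_kg": float("nan"), "pr_mg_kg_day": float("nan"),
            "flux_status": "missing" if not fit.ok else "ok",
        }
        if fit.ok:
            try:
                subj = synthetic.SubjectRecord.from_series(
                    subjects[subjects["subject_id"] == sid].iloc[0]
                )
                flux = kinetics.cholesterol_flux(subj, fit)
                row.update(
                    pool_size_mg_kg=flux.pool_size_mg_kg,
                    pr_mg_kg_day=flux.pr_mg_kg_day,
                )
            except MissingDataError as exc:
                row["flux_status"] = f"missing ({exc})"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics surfaces


def _group_values(frame: pd.DataFrame, col: str, group: str) -> np.ndarray:
    v = frame.loc[frame["group"] == group, col].to_numpy(dtype=float)
    return v[~np.isnan(v)]


def _safe_compare(x, y, settings: StatsSettings, how: str, seed: int):
    try:
        if how == "yuen":
            r = robust.yuen_bootstrap(x, y, settings.trim, settings.n_boot, seed)
        else:
            r = robust.t_test(x, y)
        return r.p_value, r.ci
    except Exception:  # degenerate/short samples -> NA comparison
        return float("nan"), (float("nan"), float("nan"))


def _table1(subjects: pd.DataFrame, settings: StatsSettings) -> pd.DataFrame:
    frame = subjects.copy()
    if {"glucose_mg_dl", "insulin_miu_l"} <= set(frame.columns):
        frame["homa_ir"] = [
            robust.homa_ir(g, i) if g > 0 and i > 0 else float("nan")
            for g, i in zip(frame["glucose_mg_dl"], frame["insulin_miu_l"])
        ]
    rows = []
    covariates = [c for c in frame.columns if c not in ("subject_id", "group")]
    for i, cov in enumerate(covariates):
        ctrl = _group_values(frame, cov, "control")
        t2d = _group_values(frame, cov, "t2d")
        if not len(ctrl) or not len(t2d):
            continue
        dc, dt = robust.descriptives(ctrl), robust.descriptives(t2d)
        p, _ = _safe_compare(t2d, ctrl, settings, "yuen", settings.seed + i)
        rows.append(
            {
                "variable": cov,
                "t2d_median": dt["median"], "t2d_min": dt["min"], "t2d_max": dt["max"],
                "control_median": dc["median"], "control_min": dc["min"], "control_max": dc["max"],
                "p_value": p, "method": "yuen_bootstrap", "note": _NOTE,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    protein_kinetics: pd.DataFrame,
    cholesterol_kinetics: pd.DataFrame,
    settings: StatsSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group comparison tables: cholesterol kinetics (unpaired t) and
    protein half-lives (Yuen with percentile bootstrap).

    Proteins quantified in only one group are reported with an NA
    comparison rather than dropped.
    """
    settings = settings or StatsSettings()
    # --- cholesterol (table 2)
    rows2 = []
    how2 = settings.table_tests.get("table2", "t_test")
    for label, col in [
        ("HDL cholesterol pool (mg/kg)", "pool_size_mg_kg"),
        ("HDL cholesterol FCR (1/day)", "fcr_per_day"),
        ("HDL cholesterol residence time (day)", "residence_time_d"),
        ("HDL cholesterol PR (mg/kg/d)", "pr_mg_kg_day"),
    ]:
        if col not in cholesterol_kinetics.columns:
            continue
        ok = cholesterol_kinetics[cholesterol_kinetics["ok"] == True]  # noqa: E712
        ctrl, t2d = _group_values(ok, col, "control"), _group_values(ok, col, "t2d")
        p, _ = (
            _safe_compare(t2d, ctrl, settings, how2, settings.seed)
            if len(ctrl) >= 2 and len(t2d) >= 2
            else (float("nan"), None)
        )
        rows2.append(
            {
                "variable": label,
                "control_mean": ctrl.mean() if len(ctrl) else float("nan"),
                "control_sd": ctrl.std(ddof=1) if len(ctrl) > 1 else float("nan"),
                "t2d_mean": t2d.mean() if len(t2d) else float("nan"),
                "t2d_sd": t2d.std(ddof=1) if len(t2d) > 1 else float("nan"),
                "p_value": p, "method": how2, "note": _NOTE,
            }
        )
    table2 = pd.DataFrame(rows2)

    # --- proteins (table 3)
    rows3 = []
    how3 = settings.table_tests.get("table3", "yuen")
    ok = protein_kinetics[protein_kinetics["ok"] == True]  # noqa: E712
    for j, (acc, grp) in enumerate(sorted(ok.groupby("accession"))):
        ctrl = _group_values(grp, "half_life_h", "control")
        t2d = _group_values(grp, "half_life_h", "t2d")
        if len(ctrl) >= 2 and len(t2d) >= 2:
            p, ci = _safe_compare(t2d, ctrl, settings, how3, settings.seed + 100 + j)
        else:
            p, ci = float("nan"), (float("nan"), float("nan"))
        rows3.append(
            {
                "accession": acc,
                "protein": grp["protein"].iloc[0],
                "method": grp["method"].mode().iloc[0] if len(grp) else "?",
                "control_t_half_h": ctrl.mean() if len(ctrl) else float("nan"),
                "control_sd_h": ctrl.std(ddof=1) if len(ctrl) > 1 else float("nan"),
                "control_n": len(ctrl),
                "t2d_t_half_h": t2d.mean() if len(t2d) else float("nan"),
                "t2d_sd_h": t2d.std(ddof=1) if len(t2d) > 1 else float("nan"),
                "t2d_n": len(t2d),
                "p_value": p, "ci_low": ci[0], "ci_high": ci[1],
                "test": how3, "note": _NOTE,
            }
        )
    return table2, pd.DataFrame(rows3)


_ASSOCIATIONS = [
    # (label, y: (table, accession/col), x covariate, subset group or None)
    ("ApoA-II FCR vs HbA1c", "P02652", "hba1c_percent", None),
    ("ApoA-IV FCR vs HbA1c", "P06727", "hba1c_percent", None),
    ("CETP activity vs adiponectin", "cetp_activity_pmol_ml_min", "adiponectin_ug_ml", "t2d"),
    ("ApoA-II FCR vs proinflammatory index", "P02652", "proinflammatory_index", "t2d"),
    ("PON1 FCR vs LCAT activity", "P27169", "lcat_activity", "t2d"),
]

_CORRELATIONS = [
    ("LCAT activity vs blood glucose", "lcat_activity", "glucose_mg_dl", "t2d"),
    ("Proinflammatory index vs HDL cholesterol", "proinflammatory_index", "hdl_cholesterol_mg_dl", "t2d"),
]


def association_analyses(
    protein_kinetics: pd.DataFrame,
    subjects: pd.DataFrame,
    settings: StatsSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlation and regression surfaces (tables 4-5, figure 2-3 data).

    Protein FCRs enter the regressions per hour.  Returns
    ``(table4, table5, figure2_data, figure3_data)``; rows with fewer
    than 5 usable pairs are reported as NA with the reason.
    """
    settings = settings or StatsSettings()
    ok = protein_kinetics[protein_kinetics["ok"] == True]  # noqa: E712
    merged = subjects.copy()

    def protein_fcr(acc: str) -> pd.Series:
        sub = ok[ok["accession"] == acc].set_index("subject_id")["fcr_per_h"]
        return merged["subject_id"].map(sub)

    rows4 = []
    for i, (label, ycol, xcol, group) in enumerate(_CORRELATIONS):
        frame = merged if group is None else merged[merged["group"] == group]
        if ycol not in frame.columns or xcol not in frame.columns:
            continue
        pairs = frame[[xcol, ycol]].dropna()
        if len(pairs) < 5:
            rows4.append({"parameters": label, "r_pb": float("nan"), "p_value": float("nan"),
                          "ci_low": float("nan"), "ci_high": float("nan"),
                          "n": len(pairs), "reason": "fewer than 5 pairs", "note": _NOTE})
            continue
        res = robust.percentage_bend_cor(
            pairs[xcol], pairs[ycol], n_boot=settings.n_boot, seed=settings.seed + 200 + i
        )
        rows4.append({"parameters": label, "r_pb": res.r_pb, "p_value": res.p_value,
                      "ci_low": res.ci[0], "ci_high": res.ci[1], "n": res.n,
                      "reason": "", "note": _NOTE})
    table4 = pd.DataFrame(rows4)

    rows5, fig2_rows, fig3_rows = [], [], []
    for i, (label, target, xcol, group) in enumerate(_ASSOCIATIONS):
        frame = merged if group is None else merged[merged["group"] == group]
        y = protein_fcr(target) if target in set(ok["accession"]) else (
            merged[target] if target in merged.columns else None
        )
        if y is None or xcol not in merged.columns:
            continue
        data = pd.DataFrame({"x": merged[xcol], "y": y, "group": merged["group"],
                             "subject_id": merged["subject_id"]})
        if group is not None:
            data = data[data["group"] == group]
        data = data.dropna(subset=["x", "y"])
        if len(data) < 5:
            rows5.append({"parameters": label, "slope": float("nan"), "intercept": float("nan"),
                          "ci_low": float("nan"), "ci_high": float("nan"), "n": len(data),
                          "reason": "fewer than 5 pairs", "note": _NOTE})
            continue
        res = robust.theil_sen(
            data["x"], data["y"], n_boot=settings.n_boot, seed=settings.seed + 300 + i
        )
        rows5.append({"parameters": label, "slope": res.slope, "intercept": res.intercept,
                      "ci_low": res.slope_ci[0], "ci_high": res.slope_ci[1],
                      "n": res.n, "reason": "", "note": _NOTE})
        if "HbA1c" in label:
            fig2_rows.append(data.assign(panel=label))
        if "adiponectin" in label:
            fig3_rows.append(data.assign(panel=label))
    table5 = pd.DataFrame(rows5)
    figure2 = pd.concat(fig2_rows, ignore_index=True) if fig2_rows else pd.DataFrame()
    figure3 = pd.concat(fig3_rows, ignore_index=True) if fig3_rows else pd.DataFrame()
    return table4, table5, figure2, figure3


def _figure1(tables: Mapping[str, pd.DataFrame], subjects: pd.DataFrame) -> pd.DataFrame:
    chol = tables["cholesterol"].merge(
        subjects[["subject_id", "group"]], on="subject_id", how="left"
    )
    per_subject = (
        chol.groupby(["group", "subject_id", "time_h"])["enrichment"].mean().reset_index()
    )
    out = (
        per_subject.groupby(["group", "time_h"])["enrichment"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# run + reports


def run_study(config: RunConfig) -> CohortResult:
    """Execute a full study and return every result surface.

    Deterministic given the config (simulation seed and statistics seed);
    all QC rejections are logged, and no peptide is silently dropped:
    input peptide count equals retained plus rejected.
    """
    tables = _load_tables(config)
    subjects = tables["subjects"]
    if subjects.empty:
        raise ConfigurationError("empty cohort")
    mpe = _subject_mpe(tables)
    peptide_fits, protein_kinetics, rejections = _protein_kinetics(
        tables, subjects, mpe, config
    )
    chol = _cholesterol_kinetics(tables, subjects, config)

    table1 = _table1(subjects, config.stats)
    table2, table3 = compare_groups(protein_kinetics, chol, config.stats)
    table4, table5, fig2, fig3 = association_analyses(
        protein_kinetics, subjects, config.stats
    )
    fig1 = _figure1(tables, subjects)

    n_input = (
        len(tables["peptides"].groupby(["subject_id", "accession", "peptide"]))
        if len(tables["peptides"])
        else 0
    )
    manifest = {
        "config_hash": config.config_hash(),
        "simulation_seed": config.design.seed if config.design else None,
        "stats_seed": config.stats.seed,
        "versions": _versions(),
        "qc": {
            "peptides_in": n_input,
            "peptides_retained": n_input - len(rejections),
            "peptides_rejected": len(rejections),
            "fits_excluded_r2": int(peptide_fits["excluded"].sum()) if len(peptide_fits) else 0,
        },
        "note": _NOTE,
    }
    result = CohortResult(
        table1=table1, table2=table2, table3=table3, table4=table4, table5=table5,
        figure1=fig1, figure2=fig2, figure3=fig3,
        protein_kinetics=protein_kinetics, peptide_fits=peptide_fits,
        cholesterol_kinetics=chol, rejections=rejections, manifest=manifest,
    )
    if config.outdir:
        render_reports(result, config.outdir)
    return result


def _versions() -> dict[str, str]:
    import importlib.metadata

    out = {}
    for pkg in ("hdlflux", "numpy", "scipy", "pandas"):
        try:
            out[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def render_reports(result: CohortResult, outdir) -> list[pathlib.Path]:
    """Write one CSV per result surface plus the JSON run manifest."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = {
        "table1_covariates": result.table1,
        "table2_cholesterol_kinetics": result.table2,
        "table3_protein_half_lives": result.table3,
        "table4_correlations": result.table4,
        "table5_regressions": result.table5,
        "figure1_cholesterol_labeling": result.figure1,
        "figure2_hba1c_regressions": result.figure2,
        "figure3_adiponectin_cetp": result.figure3,
        "protein_kinetics": result.protein_kinetics,
        "peptide_fits": result.peptide_fits,
        "cholesterol_kinetics": result.cholesterol_kinetics,
        "qc_rejections": result.rejections,
    }
    for name, frame in frames.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
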
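"""Readers, writers, bundled fixtures, configuration and the pipeline.

The two cohort fixtures shipped with the package are the per-patient
characteristics table (10 rows) and the per-(patient, size class, state)
outcome table (60 rows, gradients and NFD).  Their checksums are verified
at load time.

All CSV outputs carry ``#``-prefixed header comments recording the seed
and a hash of the configuration; readers skip them.  Floats are written
at full ``repr`` precision so write-then-read round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grading, stats
from .errors import ConfigurationError, InputError, VavrError
from .grading import ReferenceRange
from .model import calibrate_eoa, vmax_from_dp
from .synthetic import CohortGenParams, make_cohort

__all__ = [
    "load_fixture",
    "load_reference_ranges",
    "load_config",
    "read_cohort_csv",
    "write_csv",
    "run_pipeline",
    "PipelineError",
]

_FIXTURE_SHA256 = {
    "table1": "5ef2049139f0fec705832f811bc365257bb6ca7a47fa6d9859b8ce957ea2bbcc",
    "table4": "05964f68af1e187a39b06bc2742b0548e34ae4c99060a7c51e695f000b597894",
}


class PipelineError(VavrError):
    """A pipeline stage failed; the message names the stage."""


def _data_bytes(name: str) -> bytes:
    return resources.files("vavr.data").joinpath(name).read_bytes()


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled cohort fixture ('table1' or 'table4').

    'table1' returns the 10 patient-characteristics rows; 'table4' the 60
    long-format outcome rows (10 patients x 3 size classes x 2 states)
    with gradient (mmHg) and NFD columns.  The file checksum is verified
    before parsing.
    """
    if name not in _FIXTURE_SHA256:
        raise InputError(
            f"unknown fixture '{name}'; available: {sorted(_FIXTURE_SHA256)}")
    raw = _data_bytes(f"{name}.csv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise InputError(f"fixture '{name}' failed its checksum "
                         f"(got {digest})")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw))


def load_reference_ranges(path: str | Path | None = None) -> dict[str, ReferenceRange]:
    """Load reference ranges from YAML (bundled defaults if no path)."""
    if path is None:
        text = _data_bytes("reference_ranges.yaml").decode()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    ranges = doc.get("reference_ranges", doc)
    out = {}
    for metric, spec in ranges.items():
        out[metric] = ReferenceRange(metric=metric, median=spec["median"],
                                     p3=spec["p3"], p97=spec["p97"],
                                     direction=spec.get("direction", "high"))
    return out


def load_config(path: str | Path) -> dict:
    """Load a pipeline YAML config."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return doc


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, *, seed=None,
              config_hash: str | None = None) -> None:
    """Write a CSV with provenance header comments, full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort/results CSV, skipping provenance comments."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def _grade_results(results: pd.DataFrame, records: pd.DataFrame | None,
                   reference_ranges: dict[str, ReferenceRange],
                   thresholds: grading.StenosisThresholds) -> pd.DataFrame:
    graded = results.copy()
    if "vmax_mps" not in graded.columns:
        graded["vmax_mps"] = graded["dp_mmhg"].map(vmax_from_dp)
    graded["stenosis_grade"] = [
        grading.stenosis_grade(v, thresholds).value for v in graded["vmax_mps"]]
    for metric in ("nfd", "wpd", "angle_deg", "vmax_mps", "dp_mmhg"):
        if metric in graded.columns and metric in reference_ranges:
            graded[f"{metric}_flag"] = [
                grading.percentile_flag(v, reference_ranges[metric]).value
                for v in graded[metric]]
    # PPM needs an EOA and a BSA; the EOA is calibrated from the resting
    # (flow, gradient) pair when a characteristics table is available.
    if records is not None and {"bsa_m2", "peak_systolic_flow_mls"} <= set(records.columns):
        info = records.set_index("patient_id")
        rest = graded[graded["state"] == "rest"].set_index(
            ["patient_id", "size_class"])["dp_mmhg"]
        eoa_est, ppm = [], []
        for _, row in graded.iterrows():
            q = info.loc[row["patient_id"], "peak_systolic_flow_mls"]
            bsa = info.loc[row["patient_id"], "bsa_m2"]
            dp_rest = rest.loc[(row["patient_id"], row["size_class"])]
            eoa = calibrate_eoa(q, dp_rest)
            eoa_est.append(eoa)
            ppm.append(grading.ppm_class(eoa, bsa).value)
        graded["eoa_est_cm2"] = eoa_est
        graded["ppm_class"] = ppm
    return graded


def _stats_family(results: pd.DataFrame, family: str) -> pd.DataFrame:
    """Run the paired test family on a long results table."""
    metrics = [c for c in ("dp_mmhg", "nfd", "vmax_mps", "wpd", "angle_deg")
               if c in results.columns]
    wide = results.pivot_table(index="patient_id",
                               columns=["size_class", "state"],
                               values=metrics)
    rows = []
    for metric in metrics:
        for cls in ("smaller", "reference", "larger"):
            rest = wide[(metric, cls, "rest")].to_numpy()
            stress = wide[(metric, cls, "stress")].to_numpy()
            res = stats.wilcoxon_signed_rank(rest, stress)
            rows.append({"metric": metric, "comparison": f"{cls}:rest_vs_stress",
                         "test": res.test, "statistic": res.statistic,
                         "p_value": res.p_value,
                         "relative_effect": res.relative_effect,
                         "n1": res.n1, "n2": res.n2})
        for cls in ("smaller", "larger"):
            ref = wide[(metric, "reference", "rest")].to_numpy()
            other = wide[(metric, cls, "rest")].to_numpy()
            res = stats.wilcoxon_signed_rank(ref, other)
            rows.append({"metric": metric,
                         "comparison": f"rest:{cls}_vs_reference",
                         "test": res.test, "statistic": res.statistic,
                         "p_value": res.p_value,
                         "relative_effect": res.relative_effect,
                         "n1": res.n1, "n2": res.n2})
    table = pd.DataFrame(rows)
    if family == "all":
        table["p_adjusted"] = stats.bh_adjust(table["p_value"].to_numpy())
    elif family == "per_metric":
        table["p_adjusted"] = np.nan
        for metric in table["metric"].unique():
            sel = table["metric"] == metric
            table.loc[sel, "p_adjusted"] = stats.bh_adjust(
                table.loc[sel, "p_value"].to_numpy())
    else:
        raise ConfigurationError(f"unknown stats family '{family}'")
    return table


def _summary_report(summary: pd.DataFrame) -> str:
    """Render the median summary in the rest/stress per-size layout."""
    lines = ["Cohort medians (rest/stress) by valve size class", ""]
    header = f"{'parameter':<12}" + "".join(
        f"{cls:>18}" for cls in ("smaller", "reference", "larger"))
    lines.append(header)
    for metric in summary["metric"].unique():
        cells = []
        for cls in ("smaller", "reference", "larger"):
            sub = summary[(summary["metric"] == metric)
                          & (summary["size_class"] == cls)]
            rest = sub[sub["state"] == "rest"]["median"]
            stress = sub[sub["state"] == "stress"]["median"]
            if len(rest) and len(stress):
                cells.append(f"{rest.iloc[0]:g}/{stress.iloc[0]:g}")
            elif len(rest):
                cells.append(f"{rest.iloc[0]:g}")
            else:
                cells.append("-")
        lines.append(f"{metric:<12}" + "".join(f"{c:>18}" for c in cells))
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Run cohort -> grading -> stats -> summary and write the bundle.

    ``config`` keys: ``source`` (``{"fixture": "table4"}`` or
    ``{"synthetic": {...CohortGenParams fields...}}``), optional
    ``reference_ranges`` (path), ``grading_thresholds``, ``stats``
    (``{"family": "per_metric" | "all"}``) and ``seed``.

    Outputs ``cohort.csv``, ``grading.csv``, ``stats.csv``,
    ``summary.csv`` and ``report.txt`` in ``out_dir``; on a stage failure
    all partial outputs are removed and the error names the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    chash = _config_hash(config)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = out_dir / name
        write_csv(df, path, seed=seed, config_hash=chash)
        written.append(path)
        return path

    stage = "configure"
    try:
        source = config.get("source", {"fixture": "table4"})
        thresholds = grading.StenosisThresholds(
            **config.get("grading_thresholds", {}))
        ranges = load_reference_ranges(config.get("reference_ranges"))
        family = config.get("stats", {}).get("family", "per_metric")

        stage = "cohort"
        if "fixture" in source:
            results = load_fixture(source["fixture"])
            records = load_fixture("table1")
        elif "synthetic" in source:
            gen = dict(source["synthetic"])
            if seed is not None:
                gen.setdefault("seed", seed)
            if "eoa_by_size" in gen:
                gen["eoa_by_size"] = {int(k): float(v)
                                      for k, v in gen["eoa_by_size"].items()}
            for key in ("flow_range", "nfd_distribution", "wpd_distribution",
                        "angle_distribution", "jet_center_offset"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            records, results = make_cohort(CohortGenParams(**gen))
        else:
            raise ConfigurationError(
                "config.source must name a 'fixture' or 'synthetic' cohort")
        paths = {"cohort": emit(results, "cohort.csv"),
                 "records": emit(records, "records.csv")}

        stage = "grading"
        graded = _grade_results(results, records, ranges, thresholds)
        paths["grading"] = emit(graded, "grading.csv")

        stage = "stats"
        stat_table = _stats_family(results, family)
        paths["stats"] = emit(stat_table, "stats.csv")

        stage = "summary"
        summary = stats.summarize_cohort(results)
        paths["summary"] = emit(summary, "summary.csv")
        report = out_dir / "report.txt"
        report.write_text(f"# seed={seed} config={chash}\n\n"
                          + _summary_report(summary))
        written.append(report)
        paths["report"] = report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return paths
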
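"""Structure–digestibility correlation table.

Each sample condition (e.g. untreated biomass and material pretreated in
different reactor configurations) is summarized by one row: enzymatic
glucan release, composition (xylan, lignin), cellulose degree of
polymerization, and the four image-derived structural parameters (mean
particle area, aspect ratio, cell wall thickness, surface roughness,
delamination/porosity).  Every parameter is then correlated with glucan
release by the Pearson product-moment coefficient R, and R² reported
alongside.

With three or four samples per study these correlations are descriptive
ranking statistics, not inference — no p-values are computed.  The
default sample set excludes the untreated control, restricting the
comparison to the pretreated conditions; the all-samples mode is also
available, since either choice can be scientifically defensible
depending on the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleSummary",
    "CorrelationTable",
    "STRUCTURAL_PARAMETERS",
    "pearson_r",
    "build_correlation_table",
    "render_report",
    "summaries_to_frame",
    "read_summaries",
]

#: parameters correlated against the response, in report order
STRUCTURAL_PARAMETERS = (
    "xylan",
    "lignin",
    "degree_of_polymerization",
    "particle_size",
    "aspect_ratio",
    "cell_wall_thickness",
    "surface_roughness",
    "delamination_porosity",
)


@dataclass
class SampleSummary:
    """One sample condition's composition, digestibility and structure.

    Percentages are on the 0–100 scale; ``particle_size`` is the mean
    projected particle area in mm²; ``cell_wall_thickness`` in µm;
    ``surface_roughness`` in grayscale-SD units; missing measurements
    are NaN.
    """

    sample_id: str
    glucan_release: float = np.nan
    xylan: float = np.nan
    lignin: float = np.nan
    degree_of_polymerization: float = np.nan
    particle_size: float = np.nan
    aspect_ratio: float = np.nan
    cell_wall_thickness: float = np.nan
    surface_roughness: float = np.nan
    delamination_porosity: float = np.nan
    pretreated: bool = True

    def __post_init__(self) -> None:
        for name in ("glucan_release", "xylan", "lignin", "delamination_porosity"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass
class CorrelationTable:
    table: pd.DataFrame  # parameter, R, R2, n, per-parameter
    response: str
    sample_set: str  # "pretreated-only" or "all"

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        """Display copy rounded half-away-from-zero; unrounded values
        stay in ``table``."""
        out = self.table.copy()

        def _round(v):
            if not np.isfinite(v):
                return v
            scale = 10**ndigits
            return np.sign(v) * np.floor(abs(v) * scale + 0.5) / scale

        out["R"] = out["R"].map(_round)
        out["R2"] = out["R2"].map(_round)
        return out


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def summaries_to_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    cols = [f.name for f in dc_fields(SampleSummary)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])


def read_summaries(path: str | Path) -> list[SampleSummary]:
    """Read sample summaries from a CSV with SampleSummary's columns."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {"sample_id": str(row["sample_id"])}
        for name in STRUCTURAL_PARAMETERS + ("glucan_release",):
            if name in row and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        if "pretreated" in row and pd.notna(row["pretreated"]):
            kwargs["pretreated"] = bool(row["pretreated"])
        out.append(SampleSummary(**kwargs))
    return out


def build_correlation_table(
    summaries: list[SampleSummary],
    response: str = "glucan_release",
    sample_set: str = "pretreated-only",
) -> CorrelationTable:
    """Correlate every structural/compositional parameter with the response.

    ``sample_set="pretreated-only"`` (default) drops rows with
    ``pretreated=False``; ``"all"`` keeps every row.  A parameter missing
    in some rows is correlated over the rows where both it and the
    response are present; parameters with fewer than 2 usable rows (or a
    constant series) get NaN entries rather than raising.
    """
    if sample_set == "pretreated-only":
        rows = [s for s in summaries if s.pretreated]
    elif sample_set == "all":
        rows = list(summaries)
    else:
        raise ValueError("sample_set must be 'pretreated-only' or 'all'")
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 samples in set {sample_set!r}")
    df = summaries_to_frame(rows)
    resp = df[response].to_numpy(dtype=float)

    records = []
    for param in STRUCTURAL_PARAMETERS:
        if param == response:
            continue
        vals = df[param].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(resp)
        n = int(ok.sum())
        if n < 2 or np.ptp(vals[ok]) == 0 or np.ptp(resp[ok]) == 0:
            r = np.nan
        else:
            r = pearson_r(resp[ok], vals[ok])
        records.append({"parameter": param, "R": r, "R2": r * r, "n": n})
    table = pd.DataFrame(records)
    return CorrelationTable(table=table, response=response, sample_set=sample_set)


def render_report(
    table: CorrelationTable,
    summaries: list[SampleSummary],
    out_csv: str | Path | None = None,
    out_txt: str | Path | None = None,
) -> str:
    """Emit the correlation matrix as CSV and a human-readable text block.

    The CSV carries unrounded values plus provenance columns (response,
    sample set, n); the text report shows values rounded to 2 decimal
    places, flagging missing cells.
    """
    csv_df = table.table.copy()
    csv_df["response"] = table.response
    csv_df["sample_set"] = table.sample_set
    if out_csv is not None:
        csv_df.to_csv(out_csv, index=False)

    disp = table.rounded(2)
    lines = [
        f"Correlations vs {table.response} "
        f"(sample set: {table.sample_set}, rounding: 2 dp half-away-from-zero)",
        "",
        f"{'parameter':<28} {'R':>7} {'R2':>7} {'n':>4}",
    ]
    for _, row in disp.iterrows():
        r = "  n/a" if not np.isfinite(row["R"]) else f"{row['R']:7.2f}"
        r2 = "  n/a" if not np.isfinite(row["R2"]) else f"{row['R2']:7.2f}"
        lines.append(f"{row['parameter']:<28} {r:>7} {r2:>7} {int(row['n']):>4}")
    lines.append("")
    lines.append(f"samples: {', '.join(s.sample_id for s in summaries)}")
    text = "\n".join(lines)
    if out_txt is not None:
        Path(out_txt).write_text(text + "\n")
    return text
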
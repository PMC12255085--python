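"""Readers and writers shared by the CLI and library users.

CSV dialect is fixed: UTF-8, comma separator, ``.`` decimal point.  Pixel
coordinates are 0-based with half-open ROI intervals.  Design tables use the
column layout ``run_order,block,pH,salinity_ppt,<response>...``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rsm import DEFAULT_FACTORS, DesignTable, Factor, QuadraticFit
from .settling import ROI

__all__ = [
    "DesignParseError",
    "read_design_csv",
    "write_design_csv",
    "fit_to_dict",
    "fit_to_json",
    "fit_from_json",
    "anova_to_csv",
    "anova_to_text",
    "read_roi_json",
    "read_frames_dir",
    "format_p",
]

#: CSV column aliases -> canonical factor names
_FACTOR_COLUMNS = {"pH": "pH", "salinity_ppt": "salinity", "salinity": "salinity"}


class DesignParseError(ValueError):
    pass


def read_design_csv(path, factors: tuple[Factor, ...] = DEFAULT_FACTORS) -> DesignTable:
    """Parse a design/response CSV into a DesignTable, with line-level errors."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise DesignParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    canon = [_FACTOR_COLUMNS.get(h, h) for h in header]
    required = {"run_order", "block"} | {f.name for f in factors}
    missing = required - set(canon)
    if missing:
        raise DesignParseError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise DesignParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        rec = {}
        for name, cell in zip(canon, row):
            try:
                rec[name] = float(cell)
            except ValueError:
                raise DesignParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {name!r}"
                ) from None
        records.append(rec)
    if not records:
        raise DesignParseError(f"{path}: no data rows")
    df = pd.DataFrame.from_records(records)
    df["run_order"] = df["run_order"].astype(int)
    df["block"] = df["block"].astype(int)
    if df["run_order"].duplicated().any():
        dups = sorted(df.loc[df["run_order"].duplicated(), "run_order"].unique())
        raise DesignParseError(f"{path}: duplicate run_order values {dups}")
    return DesignTable(tuple(factors), df)


def write_design_csv(design: DesignTable, path) -> None:
    df = design.data.rename(columns={"salinity": "salinity_ppt"})
    df.to_csv(path, index=False)


def fit_to_dict(fit: QuadraticFit) -> dict:
    return {
        "response": fit.response_name,
        "factors": [
            {"name": f.name, "center": f.center, "step": f.step} for f in fit.factors
        ],
        "coefficients": fit.coefficients(),
        "ss": {
            "total": fit.ss_total,
            "model": fit.ss_model,
            "error": fit.ss_error,
        },
        "df": {"model": fit.df_model, "error": fit.df_error},
        "observed": fit.observed.tolist(),
        "fitted": fit.fitted.tolist(),
        "residuals": fit.residuals.tolist(),
    }


def fit_to_json(fit: QuadraticFit, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def fit_from_json(path) -> QuadraticFit:
    """Rehydrate a fit (coefficients + bookkeeping) from its JSON export."""
    d = json.loads(Path(path).read_text())
    factors = tuple(Factor(f["name"], f["center"], f["step"]) for f in d["factors"])
    coef = d["coefficients"]
    names = [f.name for f in factors]
    k = len(names)
    inter = [
        coef[f"{names[i]}*{names[j]}"] for i in range(k) for j in range(i + 1, k)
    ]
    block_items = sorted(
        (kk for kk in coef if kk.startswith("block[")),
        key=lambda s: int(s[6:-1]),
    )
    levels = [int(s[6:-1]) for s in block_items]
    observed = np.asarray(d["observed"], float)
    fitted = np.asarray(d["fitted"], float)
    return QuadraticFit(
        response_name=d["response"],
        factors=factors,
        beta0=coef["b0"],
        beta_linear=np.array([coef[nm] for nm in names]),
        beta_square=np.array([coef[f"{nm}^2"] for nm in names]),
        beta_interaction=np.array(inter),
        block_effects=np.array([coef[s] for s in block_items]),
        block_levels=levels or [1],
        term_names=list(coef),
        residuals=np.asarray(d["residuals"], float),
        fitted=fitted,
        observed=observed,
        ss_total=d["ss"]["total"],
        ss_model=d["ss"]["model"],
        ss_error=d["ss"]["error"],
        df_model=d["df"]["model"],
        df_error=d["df"]["error"],
        design_matrix=None,
    )


def format_p(p: float | None, digits: int = 3) -> str:
    if p is None:
        return ""
    floor = 10 ** (-digits)
    if p < floor:
        return f"<{floor:.{digits}f}".replace("0.", "0.", 1)
    return f"{p:.{digits}f}"


def anova_to_csv(table, path) -> None:
    df = table.to_frame()
    df["p"] = [format_p(p) for p in df["p"]]
    df.to_csv(path, index=False)


def anova_to_text(table) -> str:
    df = table.to_frame()
    lines = [f"{'Source':<40}{'DF':>4}{'Adj SS':>12}{'Adj MS':>12}{'F':>10}{'p':>9}"]
    for _, r in df.iterrows():
        ms = f"{r.adj_ms:.3f}" if pd.notna(r.adj_ms) else ""
        F = f"{r.F:.2f}" if pd.notna(r.F) else ""
        p = format_p(r.p if pd.notna(r.p) else None)
        star = "*" if r.significant else ""
        lines.append(
            f"{r.source:<40}{int(r.df):>4}{r.adj_ss:>12.3f}{ms:>12}{F:>10}{p:>8}{star}"
        )
    return "\n".join(lines)


def read_roi_json(path) -> ROI:
    d = json.loads(Path(path).read_text())
    return ROI(x0=int(d["x0"]), y0=int(d["y0"]), width=int(d["width"]), height=int(d["height"]))


def read_frames_dir(directory) -> list[tuple[float, np.ndarray]]:
    """Load ``frames.csv`` (``filename,time_h``) plus the referenced images."""
    import imageio.v3 as iio

    directory = Path(directory)
    index = directory / "frames.csv"
    if not index.exists():
        raise FileNotFoundError(f"{index} not found")
    df = pd.read_csv(index)
    if not {"filename", "time_h"} <= set(df.columns):
        raise DesignParseError(f"{index}: needs columns filename,time_h")
    df = df.sort_values("time_h")
    return [
        (float(row.time_h), iio.imread(directory / row.filename))
        for row in df.itertuples()
    ]
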
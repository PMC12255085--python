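"""Blocked central composite designs and quadratic response-surface analysis.

The sedimentation experiments this package supports vary two factors (culture
pH and NaCl salinity) in a two-block central composite design (CCD): one block
holds the 2x2 factorial ("cube") points plus replicated centre runs, the other
the axial ("star") points plus their own centre runs.  Responses (settling
efficiency in %, settling time in hours) are fitted to the full second-order
polynomial

    y = b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2 + block + e

by ordinary least squares with a sum-to-zero block contrast, so ``b0`` is the
blocks-averaged intercept and the printed equation predicts for an "average"
block.  ANOVA uses Type-III (adjusted) sums of squares computed on the coded
design matrix — the convention of the major RSM packages — while the fitted
equation itself is reported in actual engineering units.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _sopt
from scipy import stats as _sstats

__all__ = [
    "Factor",
    "DesignTable",
    "QuadraticFit",
    "AnovaTable",
    "ModelSummary",
    "OptimizationResult",
    "ValidationResult",
    "DEFAULT_FACTORS",
    "RankDeficiencyError",
    "build_ccd",
    "coded_to_actual",
    "actual_to_coded",
    "fit_quadratic",
    "predict",
    "anova_table",
    "model_summary",
    "optimize_responses",
    "linreg_validation",
    "spearman_rho",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when the quadratic design matrix is singular."""


@dataclass(frozen=True)
class Factor:
    """Linear map between coded CCD levels and actual factor units.

    ``actual(c) = center + c * step`` — e.g. pH has centre 7 and step 1.5 per
    coded unit, so coded -2..+2 spans pH 4..10.
    """

    name: str
    center: float
    step: float
    low_label: int = -2
    high_label: int = 2

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")

    def to_actual(self, coded):
        return self.center + np.asarray(coded, dtype=float) * self.step

    def to_coded(self, actual):
        return (np.asarray(actual, dtype=float) - self.center) / self.step


#: pH 4..10 and salinity 5..35 ppt over coded -2..+2 (study factor levels).
DEFAULT_FACTORS: tuple[Factor, ...] = (
    Factor("pH", 7.0, 1.5),
    Factor("salinity", 20.0, 7.5),
)


def coded_to_actual(factor: Factor, c: float) -> float:
    return float(factor.to_actual(c))


def actual_to_coded(factor: Factor, a: float) -> float:
    return float(factor.to_coded(a))


@dataclass
class DesignTable:
    """A designed experiment: factor settings in actual units plus responses.

    ``data`` holds one row per run with columns ``run_order``, ``block``, one
    column per factor (actual units, named after the factor) and any number of
    response columns.
    """

    factors: tuple[Factor, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        required = ["run_order", "block"] + [f.name for f in self.factors]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.data["run_order"].duplicated().any():
            dup = self.data.loc[self.data["run_order"].duplicated(), "run_order"]
            raise ValueError(f"duplicate run_order values: {sorted(set(dup))}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def response_names(self) -> list[str]:
        skip = {"run_order", "block", *self.factor_names}
        return [c for c in self.data.columns if c not in skip]

    def actual(self) -> np.ndarray:
        return self.data[self.factor_names].to_numpy(dtype=float)

    def coded(self) -> np.ndarray:
        return np.column_stack(
            [f.to_coded(self.data[f.name].to_numpy(float)) for f in self.factors]
        )

    def blocks(self) -> np.ndarray:
        return self.data["block"].to_numpy(int)


def build_ccd(
    factors: tuple[Factor, ...] = DEFAULT_FACTORS,
    cube_coded: int = 2,
    axial_coded: int = 1,
    n_center_cube: int = 3,
    n_center_axial: int = 3,
    seed: int = 0,
) -> DesignTable:
    """Construct a two-block CCD for two factors.

    Block 1 is the full 2^2 factorial at coded ``±cube_coded`` plus
    ``n_center_cube`` centre replicates; block 2 holds the four axial points at
    ``±axial_coded`` plus ``n_center_axial`` centre replicates.  Run order is
    randomized within blocks by ``seed``.  The defaults (cube at ±2, axial at
    ±1) reproduce the geometry of the sedimentation study, which inverts the
    textbook circumscribed CCD (cube ±1, axial ±2 — available by swapping the
    two radii).
    """
    factors = tuple(factors)
    if len(factors) != 2:
        raise ValueError(
            f"unsupported design: build_ccd handles exactly two factors, got {len(factors)}"
        )
    if cube_coded not in (1, 2) or axial_coded not in (1, 2):
        raise ValueError("cube_coded and axial_coded must be 1 or 2")
    if n_center_cube < 0 or n_center_axial < 0:
        raise ValueError("center counts must be >= 0")
    if cube_coded == axial_coded:
        warnings.warn(
            "cube and axial radii coincide: the star duplicates factorial spacing "
            "(degenerate CCD)",
            stacklevel=2,
        )

    cube = [(s1 * cube_coded, s2 * cube_coded) for s1, s2 in itertools.product((-1, 1), repeat=2)]
    axial = [(-axial_coded, 0), (axial_coded, 0), (0, -axial_coded), (0, axial_coded)]
    block1 = cube + [(0, 0)] * n_center_cube
    block2 = axial + [(0, 0)] * n_center_axial

    rng = np.random.default_rng(seed)
    rows = []
    for block_id, pts in ((1, block1), (2, block2)):
        pts = [pts[i] for i in rng.permutation(len(pts))]
        for c in pts:
            rows.append((block_id, c))
    records = []
    for run, (block_id, coded) in enumerate(rows, start=1):
        rec = {"run_order": run, "block": block_id}
        for f, c in zip(factors, coded):
            rec[f.name] = coded_to_actual(f, c)
        records.append(rec)
    return DesignTable(factors, pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# quadratic model fitting


def _surface_terms(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Full second-order model columns (no intercept) for a 2-factor matrix."""
    k = x.shape[1]
    cols = [x[:, i] for i in range(k)]
    labels = list(names)
    for i in range(k):
        cols.append(x[:, i] ** 2)
        labels.append(f"{names[i]}^2")
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(x[:, i] * x[:, j])
            labels.append(f"{names[i]}*{names[j]}")
    return np.column_stack(cols), labels


def _block_contrasts(blocks: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Sum-to-zero (deviation) contrast columns, one per block except the last."""
    levels = sorted(set(int(b) for b in blocks))
    cols = []
    for lev in levels[:-1]:
        col = np.where(blocks == lev, 1.0, np.where(blocks == levels[-1], -1.0, 0.0))
        cols.append(col)
    return (np.column_stack(cols) if cols else np.empty((len(blocks), 0))), levels


@dataclass
class QuadraticFit:
    """OLS fit of the full quadratic surface (actual units) with block effects."""

    response_name: str
    factors: tuple[Factor, ...]
    beta0: float
    beta_linear: np.ndarray
    beta_square: np.ndarray
    beta_interaction: np.ndarray  # upper-triangle order, length k(k-1)/2
    block_effects: np.ndarray  # one per block level, sums to zero
    block_levels: list[int]
    term_names: list[str]
    residuals: np.ndarray
    fitted: np.ndarray
    observed: np.ndarray
    ss_total: float
    ss_model: float
    ss_error: float
    df_model: int
    df_error: int
    design_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.observed)

    def coefficients(self) -> dict[str, float]:
        """Term-keyed coefficients: b0, linear, square, interaction, block[i]."""
        out = {"b0": self.beta0}
        names = [f.name for f in self.factors]
        for nm, b in zip(names, self.beta_linear):
            out[nm] = float(b)
        for nm, b in zip(names, self.beta_square):
            out[f"{nm}^2"] = float(b)
        idx = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out[f"{names[i]}*{names[j]}"] = float(self.beta_interaction[idx])
                idx += 1
        for lev, eff in zip(self.block_levels, self.block_effects):
            out[f"block[{lev}]"] = float(eff)
        return out


def _design_matrix(design: DesignTable, include_blocks: bool, coded: bool = False):
    x = design.coded() if coded else design.actual()
    surf, labels = _surface_terms(x, design.factor_names)
    cols = [np.ones(design.n_runs), surf]
    names = ["b0"] + labels
    levels: list[int] = []
    if include_blocks:
        bc, levels = _block_contrasts(design.blocks())
        if bc.shape[1]:
            cols.append(bc)
            names += [f"block[{lev}]" for lev in levels[:-1]]
    X = np.column_stack(cols)
    return X, names, levels


def fit_quadratic(
    design: DesignTable, response: str, include_blocks: bool = True
) -> QuadraticFit:
    """Fit the full second-order polynomial to one response by OLS.

    The model matrix is ``[1, x1, x2, x1^2, x2^2, x1*x2]`` in actual units plus
    sum-to-zero block contrasts, so the intercept is the blocks-averaged one and
    the coefficient vector is directly comparable with a published uncoded
    regression equation.
    """
    if response not in design.response_names:
        raise KeyError(f"response {response!r} not in design ({design.response_names})")
    y = design.data[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"response {response!r} has missing values")
    X, names, levels = _design_matrix(design, include_blocks)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} terms, have {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the terms loading on the null space
        _, s, vt = np.linalg.svd(X)
        null = vt[-1]
        guilty = [names[i] for i in np.argsort(-np.abs(null))[:2]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear terms include {guilty}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    ssm = sst - sse

    k = len(design.factors)
    n_int = k * (k - 1) // 2
    beta0 = float(beta[0])
    bl = beta[1 : 1 + k]
    bs = beta[1 + k : 1 + 2 * k]
    bi = beta[1 + 2 * k : 1 + 2 * k + n_int]
    if include_blocks and levels:
        raw = beta[1 + 2 * k + n_int :]
        effects = np.append(raw, -raw.sum())
    else:
        levels = sorted(set(design.blocks().tolist()))
        effects = np.zeros(len(levels))
    return QuadraticFit(
        response_name=response,
        factors=design.factors,
        beta0=beta0,
        beta_linear=np.asarray(bl, float),
        beta_square=np.asarray(bs, float),
        beta_interaction=np.asarray(bi, float),
        block_effects=np.asarray(effects, float),
        block_levels=list(levels),
        term_names=names,
        residuals=resid,
        fitted=fitted,
        observed=y,
        ss_total=sst,
        ss_model=ssm,
        ss_error=sse,
        df_model=p - 1,
        df_error=n - p,
        design_matrix=X,
    )


def predict(fit: QuadraticFit, actual_point) -> float:
    """Evaluate the fitted surface (blocks-averaged) at a point in actual units."""
    pt = np.asarray(actual_point, dtype=float)
    k = len(fit.factors)
    if pt.shape != (k,):
        raise ValueError(f"expected a point of dimension {k}, got shape {pt.shape}")
    coded = np.array([f.to_coded(v) for f, v in zip(fit.factors, pt)])
    if np.any(np.abs(coded) > 2 + 1e-9):
        warnings.warn(
            f"prediction point {pt.tolist()} lies outside the coded [-2, 2] design box",
            stacklevel=2,
        )
    val = fit.beta0 + float(fit.beta_linear @ pt) + float(fit.beta_square @ (pt**2))
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            val += float(fit.beta_interaction[idx]) * pt[i] * pt[j]
            idx += 1
    return float(val)


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaRow:
    source: str
    df: int
    adj_ss: float
    adj_ms: float | None
    F: float | None
    p: float | None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    alpha: float = 0.1
    lack_of_fit_estimable: bool = True

    def __getitem__(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "df": r.df,
                    "adj_ss": r.adj_ss,
                    "adj_ms": r.adj_ms,
                    "F": r.F,
                    "p": r.p,
                    "significant": (r.p is not None and r.p < self.alpha),
                }
                for r in self.rows
            ]
        )


def _sse_of(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def pure_error_split(design: DesignTable, response: str) -> tuple[float, int]:
    """Pure-error SS and df from replicated settings within each block."""
    y = design.data[response].to_numpy(float)
    key = list(zip(design.blocks(), map(tuple, design.actual())))
    groups: dict = {}
    for k_, v in zip(key, y):
        groups.setdefault(k_, []).append(v)
    ss = 0.0
    df = 0
    for vals in groups.values():
        if len(vals) > 1:
            arr = np.asarray(vals)
            ss += float(np.sum((arr - arr.mean()) ** 2))
            df += len(vals) - 1
    return ss, df


def anova_table(fit: QuadraticFit, design: DesignTable, alpha: float = 0.1) -> AnovaTable:
    """Type-III ANOVA with lack-of-fit / pure-error split.

    Adjusted SS for each term is the SSE increase when that term (or pooled
    group of terms) is dropped from the full model, computed on the *coded*
    design matrix — the convention under which the per-factor linear SS of a
    blocked CCD decompose the pooled linear SS.  Pooled rows (Linear, Square)
    drop their whole group jointly.  The default alpha of 0.1 reflects the 90%
    confidence level conventionally applied to small response-surface models.
    """
    y = fit.observed
    include_blocks = len(fit.block_levels) > 1 and np.any(fit.block_effects != 0)
    Xc, names, _levels = _design_matrix(design, include_blocks, coded=True)
    sse_full = _sse_of(Xc, y)
    sst = fit.ss_total
    n, p = Xc.shape
    df_error = n - p
    if df_error <= 0:
        raise ValueError("saturated model: no error degrees of freedom")
    mse = sse_full / df_error

    fnames = design.factor_names
    k = len(fnames)
    col = {nm: i for i, nm in enumerate(names)}

    def drop(terms: list[str]) -> float:
        idx = [col[t] for t in terms]
        keep = [i for i in range(p) if i not in idx]
        return _sse_of(Xc[:, keep], y) - sse_full

    def row(source, df, ss, use_ms_denom=mse):
        if ss is None or df == 0:
            return AnovaRow(source, df, ss if ss is not None else 0.0, None, None, None)
        ms = ss / df
        if use_ms_denom is None or use_ms_denom <= 0:
            return AnovaRow(source, df, ss, ms, None, None)
        F = ms / use_ms_denom
        pval = float(_sstats.f.sf(F, df, df_error))
        return AnovaRow(source, df, ss, ms, F, pval)

    rows: list[AnovaRow] = []
    degenerate = sst <= 1e-12
    denom = None if (degenerate or mse == 0 and sse_full == 0 and sst == 0) else mse
    if degenerate:
        warnings.warn("response is constant: all sums of squares are zero", stacklevel=2)
        denom = None

    rows.append(row("Model", p - 1, sst - sse_full, denom))
    if include_blocks:
        block_terms = [nm for nm in names if nm.startswith("block[")]
        rows.append(row("Blocks", len(block_terms), drop(block_terms), denom))
    lin_terms = list(fnames)
    rows.append(row("Linear", k, drop(lin_terms), denom))
    for nm in fnames:
        rows.append(row(f"  {nm}", 1, drop([nm]), denom))
    sq_terms = [f"{nm}^2" for nm in fnames]
    rows.append(row("Square", k, drop(sq_terms), denom))
    for nm in sq_terms:
        rows.append(row(f"  {nm}", 1, drop([nm]), denom))
    int_terms = [f"{fnames[i]}*{fnames[j]}" for i in range(k) for j in range(i + 1, k)]
    if int_terms:
        rows.append(row("2-way interaction", len(int_terms), drop(int_terms), denom))
        for nm in int_terms:
            rows.append(row(f"  {nm}", 1, drop([nm]), denom))

    rows.append(AnovaRow("Error", df_error, sse_full, mse if not degenerate else None, None, None))
    pe_ss, pe_df = pure_error_split(design, fit.response_name)
    lof_ss = sse_full - pe_ss
    lof_df = df_error - pe_df
    estimable = pe_df > 0 and lof_df > 0
    if estimable:
        mspe = pe_ss / pe_df
        if mspe > 0:
            F_lof = (lof_ss / lof_df) / mspe
            p_lof = float(_sstats.f.sf(F_lof, lof_df, pe_df))
        else:
            F_lof = p_lof = None
        rows.append(AnovaRow("Lack-of-fit", lof_df, lof_ss, lof_ss / lof_df, F_lof, p_lof))
        rows.append(AnovaRow("Pure error", pe_df, pe_ss, mspe, None, None))
    else:
        # no replicated settings: report, never silently drop
        rows.append(AnovaRow("Lack-of-fit (not estimable: no pure-error df)",
                             lof_df, lof_ss, None, None, None))
        rows.append(AnovaRow("Pure error", pe_df, pe_ss, None, None, None))
    rows.append(AnovaRow("Total", n - 1, sst, None, None, None))
    return AnovaTable(rows=rows, alpha=alpha, lack_of_fit_estimable=estimable)


# ---------------------------------------------------------------------------
# model summary diagnostics


@dataclass
class ModelSummary:
    """Regression summary: s = sqrt(MSE); R^2 family in percent.

    ``r2_pred`` is computed from PRESS (leave-one-out prediction residuals via
    leverages) and stored signed; floor at zero only when reporting.
    """

    s: float
    r2: float
    r2_adj: float
    r2_pred: float

    @property
    def r2_pred_reported(self) -> float:
        return max(self.r2_pred, 0.0)


def _leverages(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return np.sum(q * q, axis=1)


def press_statistic(fit: QuadraticFit) -> float:
    h = _leverages(fit.design_matrix)
    if np.any(h >= 1 - 1e-10):
        raise ValueError(
            "leverage-degenerate design: a run uniquely determines a parameter "
            "(h_ii ~ 1), PRESS undefined"
        )
    return float(np.sum((fit.residuals / (1 - h)) ** 2))


def model_summary(fit: QuadraticFit, design: DesignTable | None = None) -> ModelSummary:
    if fit.df_error <= 0:
        raise ValueError("no error degrees of freedom")
    sst, sse = fit.ss_total, fit.ss_error
    n = fit.n
    press = press_statistic(fit)
    s = float(np.sqrt(sse / fit.df_error))
    if sst <= 0:
        raise ValueError("constant response: R^2 undefined")
    r2 = 100.0 * (1 - sse / sst)
    r2_adj = 100.0 * (1 - (sse / fit.df_error) / (sst / (n - 1)))
    r2_pred = 100.0 * (1 - press / sst)
    return ModelSummary(s=s, r2=r2, r2_adj=r2_adj, r2_pred=r2_pred)


# ---------------------------------------------------------------------------
# multi-response optimization


@dataclass
class OptimizationResult:
    settings: np.ndarray  # actual units
    predicted: dict[str, float]
    objective_value: float
    strategy: str
    stationary_points: dict[str, np.ndarray]
    single_response_optima: dict[str, np.ndarray]


def _stationary_point(fit: QuadraticFit) -> np.ndarray | None:
    """Solve grad = 0 of the quadratic surface (2-factor closed form)."""
    k = len(fit.factors)
    A = np.diag(2.0 * fit.beta_square).astype(float)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            A[i, j] = A[j, i] = float(fit.beta_interaction[idx])
            idx += 1
    b = -fit.beta_linear.astype(float)
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None


def optimize_responses(
    fit_eff: QuadraticFit,
    fit_time: QuadraticFit,
    bounds: list[tuple[float, float]] | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    grid_step: float = 0.05,
) -> OptimizationResult:
    """Joint optimum maximizing geometric-mean desirability.

    Efficiency is larger-is-better, time smaller-is-better; each linear
    desirability is anchored at the observed min/max of that response in the
    fitted data.  A dense grid search (ties broken toward lower values of the
    second factor, then the first) is followed by a local Nelder-Mead polish.
    """
    factors = fit_eff.factors
    if bounds is None:
        bounds = [
            (coded_to_actual(f, -2), coded_to_actual(f, 2)) for f in factors
        ]
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(hi <= lo for lo, hi in bounds):
        raise ValueError(f"empty bounds: {bounds}")
    w_eff, w_time = (float(w) for w in weights)
    if w_eff < 0 or w_time < 0 or w_eff + w_time == 0:
        raise ValueError("weights must be non-negative and not both zero")

    e_lo, e_hi = float(fit_eff.observed.min()), float(fit_eff.observed.max())
    t_lo, t_hi = float(fit_time.observed.min()), float(fit_time.observed.max())

    def desirability(pt: np.ndarray) -> float:
        # linear desirabilities anchored at the observed response ranges;
        # clipped below at 0, left open above so that predictions beyond the
        # best observed response still rank (reported value is capped at 1)
        d = 1.0
        wsum = w_eff + w_time
        if w_eff > 0:
            de = max((predict(fit_eff, pt) - e_lo) / (e_hi - e_lo), 0.0)
            d *= de**w_eff
        if w_time > 0:
            dt = max((t_hi - predict(fit_time, pt)) / (t_hi - t_lo), 0.0)
            d *= dt**w_time
        return float(d ** (1.0 / wsum))

    # grid: second factor outermost ascending so argmax tie-breaks toward
    # lower salinity, then lower pH
    axes = [np.arange(lo, hi + grid_step / 2, grid_step) for lo, hi in bounds]
    best_d, best_pt = -1.0, None
    for v2 in axes[1]:
        for v1 in axes[0]:
            pt = np.array([v1, v2])
            d = desirability(pt)
            if d > best_d + 1e-12:
                best_d, best_pt = d, pt

    res = _sopt.minimize(
        lambda z: -desirability(np.clip(z, [b[0] for b in bounds], [b[1] for b in bounds])),
        best_pt,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10},
    )
    polished = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    if desirability(polished) >= best_d:
        best_pt, best_d = polished, desirability(polished)

    stationary = {}
    single = {}
    for name, fit in (("efficiency", fit_eff), ("time", fit_time)):
        sp = _stationary_point(fit)
        if sp is not None:
            stationary[fit.response_name] = sp
        sign = -1.0 if name == "efficiency" else 1.0  # minimize time, maximize eff
        best_s, best_sp = None, None
        for v2 in axes[1]:
            for v1 in axes[0]:
                val = sign * predict(fit, np.array([v1, v2]))
                if best_s is None or val < best_s - 1e-12:
                    best_s, best_sp = val, np.array([v1, v2])
        single[fit.response_name] = best_sp

    return OptimizationResult(
        settings=np.asarray(best_pt, float),
        predicted={
            fit_eff.response_name: predict(fit_eff, best_pt),
            fit_time.response_name: predict(fit_time, best_pt),
        },
        objective_value=float(min(best_d, 1.0)),
        strategy=(
            f"geometric-mean desirability (weights eff={w_eff}, time={w_time}), "
            f"grid step {grid_step} + Nelder-Mead polish"
        ),
        stationary_points=stationary,
        single_response_optima=single,
    )


# ---------------------------------------------------------------------------
# validation statistics (simple regression, correlations)


@dataclass
class ValidationResult:
    summary: ModelSummary
    slope: float
    intercept: float
    pearson_r: float
    pearson_p: float
    residuals: np.ndarray
    fitted: np.ndarray


def linreg_validation(pairs) -> ValidationResult:
    """Simple y~x regression with R^2 family (incl. PRESS-based predicted R^2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (x, y)")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    lr = _sstats.linregress(x, y)
    fitted = lr.intercept + lr.slope * x
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    press = float(np.sum((resid / (1 - h)) ** 2))
    dfe = n - 2
    if sst == 0:
        r2 = r2_adj = r2_pred = 100.0
    else:
        r2 = 100.0 * (1 - sse / sst)
        r2_adj = 100.0 * (1 - (sse / dfe) / (sst / (n - 1)))
        r2_pred = 100.0 * (1 - press / sst)
    summary = ModelSummary(
        s=float(np.sqrt(sse / dfe)), r2=r2, r2_adj=r2_adj, r2_pred=r2_pred
    )
    return ValidationResult(
        summary=summary,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        pearson_r=float(lr.rvalue),
        pearson_p=float(lr.pvalue),
        residuals=resid,
        fitted=fitted,
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = _sstats.spearmanr(x, y)
    return float(rho), float(p)
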
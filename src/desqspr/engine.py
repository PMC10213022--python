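"""Model rebuilding: OLS with validation statistics, LOO cross-validation,
donor-wise splitting, genetic-algorithm descriptor selection and
Williams-plot applicability-domain analysis.

Statistics follow the standard QSPR definitions.  With n observations,
p regressors (intercept excluded) and SSE the residual sum of squares:

    R2      = 1 - SSE/SST
    R2_adj  = 1 - (1 - R2)(n - 1)/(n - p - 1)
    S       = sqrt(SSE/(n - p - 1))         (standard error of regression)
    F       = (R2/p) / ((1 - R2)/(n - p - 1))
    RMSE    = sqrt(SSE/n)
    Q2_LOO  = 1 - PRESS/SST, PRESS from the hat-matrix shortcut
              (deleted residual = residual/(1 - h))
    AARD%   = (100/n) * sum |pred - obs| / |obs|

Standardized residuals are residual/S (no leverage correction), matching
the plain "standard residuals" convention of the source plots; the
leverage-corrected studentized variant is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .data import Dataset
from .errors import DataValidationError, FitError

FORCED_DEFAULT = ("lnP",)


def descriptor_lookup(descriptor_table) -> dict[str, float]:
    """Accept either a mapping name -> value or a long-format descriptor
    DataFrame (molecule, descriptor, value) restricted to one descriptor."""
    if isinstance(descriptor_table, Mapping):
        return dict(descriptor_table)
    df = descriptor_table
    if set(df.columns) >= {"molecule", "value"}:
        return dict(zip(df["molecule"], df["value"]))
    raise DataValidationError(
        "descriptor table must be a mapping or a frame with molecule/value columns"
    )


def build_design(
    records: Dataset,
    descriptor_table,
    include_T: bool = True,
    descriptor_name: str = "EEig02d",
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (lnP [, T] [, descriptor]) and response ln(x)."""
    lookup = descriptor_lookup(descriptor_table) if descriptor_table is not None else None
    rows, y = [], []
    for r in records.records:
        row = {"lnP": np.log(r.P_bar)}
        if include_T:
            row["T"] = r.T_K
        if lookup is not None:
            if r.hbd not in lookup:
                raise DataValidationError(
                    f"no descriptor value for donor {r.hbd!r} in the descriptor table"
                )
            row[descriptor_name] = lookup[r.hbd]
        rows.append(row)
        y.append(np.log(r.x))
    X = pd.DataFrame(rows)
    return X, pd.Series(y, name="ln_x")


@dataclass
class FitResult:
    """OLS fit plus the validation statistics of the QSPR workflow."""

    columns: tuple[str, ...]
    coef: pd.Series            # includes "intercept"
    se: pd.Series
    n: int
    p: int                     # regressors, intercept excluded
    r2: float
    r2_adj: float
    s: float
    f_stat: float
    rmse: float
    q2_loo: float
    aard_ln: float
    aard_natural: float
    residuals: np.ndarray
    fitted: np.ndarray
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.columns:
            raise FitError(
                f"design columns {tuple(X.columns)} do not match fit columns {self.columns}"
            )
        return self.coef["intercept"] + X.to_numpy() @ self.coef[list(self.columns)].to_numpy()

    def to_json(self, path=None) -> str:
        payload = {
            "columns": list(self.columns),
            "coefficients": {k: float(v) for k, v in self.coef.items()},
            "standard_errors": {k: float(v) for k, v in self.se.items()},
            "n": self.n,
            "p": self.p,
            "statistics": {
                "R2": self.r2, "R2_adj": self.r2_adj, "S": self.s, "F": self.f_stat,
                "RMSE": self.rmse, "Q2_LOO": self.q2_loo,
                "AARD_ln_percent": self.aard_ln, "AARD_natural_percent": self.aard_natural,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _design_with_intercept(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _check_design(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray]:
    if len(X) != len(y):
        raise FitError(f"X has {len(X)} rows but y has {len(y)}")
    A = _design_with_intercept(X)
    n, p1 = A.shape
    if n <= p1:
        raise FitError(f"need more than {p1} observations to fit {p1 - 1} regressors, got {n}")
    if np.linalg.matrix_rank(A) < p1:
        raise FitError("design matrix is rank deficient (collinear or constant columns)")
    yv = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(A)) or np.any(~np.isfinite(yv)):
        raise FitError("design or response contains non-finite values")
    return A, yv


def aard_percent(pred, obs, scale: str = "ln") -> float:
    """Average absolute relative deviation, percent.

    ``pred`` and ``obs`` are on the natural-log scale; ``scale='natural'``
    exponentiates before taking relative deviations.  Scale-invariant under
    a common positive rescaling of pred and obs.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if scale not in ("ln", "natural"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "natural":
        pred, obs = np.exp(pred), np.exp(obs)
    if np.any(obs == 0):
        raise FitError("AARD undefined: observation equal to zero")
    return float(100.0 / len(obs) * np.sum(np.abs(pred - obs) / np.abs(obs)))


def leverage(X: pd.DataFrame) -> np.ndarray:
    """Diagonal of the hat matrix for the intercept-augmented design."""
    A, _ = _check_design(X, np.zeros(len(X)))
    q, _ = np.linalg.qr(A)
    return np.sum(q * q, axis=1)


def q2_loo(X: pd.DataFrame, y) -> float:
    """Leave-one-out cross-validated R2 via the hat-matrix shortcut."""
    A, yv = _check_design(X, y)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        raise FitError("Q2 undefined for a constant response")
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    h = leverage(X)
    if np.any(h >= 1 - 1e-12):
        raise FitError("a point has leverage 1 and cannot be deleted")
    press = float(np.sum((resid / (1 - h)) ** 2))
    return 1.0 - press / sst


def fit_ols(X: pd.DataFrame, y) -> FitResult:
    """Ordinary least squares with the full QSPR statistics block."""
    _check_design(X, y)
    yv = np.asarray(y, dtype=float)
    model = sm.OLS(yv, sm.add_constant(X.to_numpy(dtype=float))).fit()
    n, p = len(yv), X.shape[1]
    names = ["intercept", *X.columns]
    coef = pd.Series(model.params, index=names)
    se = pd.Series(model.bse, index=names)
    fitted = np.asarray(model.fittedvalues)
    resid = yv - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - p - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    s = float(np.sqrt(sse / dof))
    f_stat = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1.0 else float("inf")
    rmse = float(np.sqrt(sse / n))
    try:
        aard_ln = aard_percent(fitted, yv, "ln")
    except FitError:       # a response of exactly 0: AARD undefined
        aard_ln = float("nan")
    return FitResult(
        columns=tuple(X.columns),
        coef=coef,
        se=se,
        n=n,
        p=p,
        r2=r2,
        r2_adj=r2_adj,
        s=s,
        f_stat=f_stat,
        rmse=rmse,
        q2_loo=q2_loo(X, yv) if sst > 0 else 1.0,
        aard_ln=aard_ln,
        aard_natural=aard_percent(fitted, yv, "natural"),
        residuals=resid,
        fitted=fitted,
        y=yv,
    )


def external_validation(fit: FitResult, X_test: pd.DataFrame, y_test) -> dict[str, float]:
    """Test-set statistics: R2 about the test mean, RMSE and AARD%."""
    if len(X_test) < 2:
        raise FitError("external validation needs at least 2 test points")
    yv = np.asarray(y_test, dtype=float)
    pred = fit.predict(X_test)
    sse = float(np.sum((yv - pred) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        raise FitError("test response is constant; R2 undefined")
    return {
        "r2": 1.0 - sse / sst,
        "rmse": float(np.sqrt(sse / len(yv))),
        "aard_ln": aard_percent(pred, yv, "ln"),
        "aard_natural": aard_percent(pred, yv, "natural"),
    }


def split_by_hbd(records: Dataset, holdout: Iterable[str]) -> tuple[Dataset, Dataset]:
    """Donor-wise train/test split: every record of a held-out donor goes to
    the test set, the remainder to training.  The partition is exact."""
    holdout = set(holdout)
    if not holdout:
        raise DataValidationError("holdout set is empty")
    present = set(records.hbds)
    unknown = holdout - present
    if unknown:
        raise DataValidationError(f"holdout donor(s) not in the dataset: {sorted(unknown)}")
    if holdout >= present:
        raise DataValidationError("holdout covers every donor; training set would be empty")
    test = [r for r in records.records if r.hbd in holdout]
    train = [r for r in records.records if r.hbd not in holdout]
    return Dataset(train, records.id), Dataset(test, records.id)


def pca_split_advisory(descriptor_table, n_suggest: int = 2) -> list[str]:
    """Suggest structurally peripheral donors to hold out for external
    validation, by distance from the centroid in the first two principal
    axes of the (standardized) descriptor matrix.  Advisory only."""
    if isinstance(descriptor_table, Mapping):
        df = pd.DataFrame({"D": descriptor_table}).sort_index()
    else:
        df = descriptor_table.pivot_table(index="molecule", columns="descriptor", values="value")
    if len(df) < 3:
        raise DataValidationError("PCA advisory needs at least 3 molecules")
    values = df.to_numpy(dtype=float)
    std = values.std(axis=0, ddof=0)
    if np.all(std == 0):
        raise DataValidationError("descriptor matrix has zero variance; PCA undefined")
    kept = std > 0
    z = (values[:, kept] - values[:, kept].mean(axis=0)) / std[kept]
    ncomp = min(2, z.shape[1], len(df) - 1)
    scores = PCA(n_components=ncomp, svd_solver="full").fit_transform(z)
    dist = np.sqrt(np.sum(scores**2, axis=1))
    # deterministic tie-break: distance descending, then name ascending
    order = sorted(zip(df.index, dist), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order[:n_suggest]]


@dataclass
class ADResult:
    """Williams-plot quantities and applicability-domain flags."""

    leverage: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    flags: list[str]            # in-domain | response outlier | structurally influential

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"leverage": self.leverage, "std_residual": self.std_residuals, "flag": self.flags}
        )


def williams_ad(
    fit: FitResult,
    X: pd.DataFrame,
    y=None,
    residual_kind: str = "standard",
) -> ADResult:
    """Applicability domain via the Williams plot.

    Warning leverage h* = 3(p+1)/n; a point is a response outlier when its
    standardized residual exceeds |3| and structurally influential when its
    leverage exceeds h*.  ``residual_kind='studentized'`` applies the
    leverage correction residual/(S*sqrt(1-h)).
    """
    h = leverage(X)
    yv = np.asarray(y, dtype=float) if y is not None else fit.y
    resid = yv - fit.predict(X)
    if residual_kind == "studentized":
        std_resid = resid / (fit.s * np.sqrt(np.clip(1 - h, 1e-12, None)))
    elif residual_kind == "standard":
        std_resid = resid / fit.s
    else:
        raise ValueError(f"unknown residual kind {residual_kind!r}")
    h_star = 3.0 * (fit.p + 1) / len(X)
    flags = []
    for hi, ri in zip(h, std_resid):
        if abs(ri) > 3:
            flags.append("response outlier")
        elif hi > h_star:
            flags.append("structurally influential")
        else:
            flags.append("in-domain")
    return ADResult(h, std_resid, h_star, flags)


def golbraikh_screen(r2: float, q2: float) -> bool:
    """Minimal acceptability screen for one-descriptor models: R2 > 0.6 and
    Q2 > 0.5."""
    return r2 > 0.6 and q2 > 0.5


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor selection.

    Defaults mirror the published workflow's scale: one structural
    descriptor beyond the forced physical variables, fitness judged by
    internal cross-validation.  The seed is mandatory.
    """

    population: int = 50
    generations: int = 100
    mutation_rate: float = 0.05
    crossover_rate: float = 0.8
    fitness: str = "q2_loo"      # or "r2"
    max_free: int = 1            # descriptors beyond the forced columns
    seed: int = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GAConfig.seed is mandatory for reproducibility")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0 <= rate <= 1:
                raise ValueError("GA rates must lie in [0, 1]")
        if self.fitness not in ("q2_loo", "r2"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


@dataclass
class GAResult:
    selected: tuple[str, ...]    # free descriptor columns chosen
    forced: tuple[str, ...]
    fit: FitResult
    fitness: float
    history: list[float]         # best fitness per generation


def _ga_fitness(X: pd.DataFrame, y, columns: Sequence[str], kind: str) -> float:
    try:
        if kind == "q2_loo":
            return q2_loo(X[list(columns)], y)
        return fit_ols(X[list(columns)], y).r2
    except FitError:
        return -np.inf


def ga_select(
    candidates: pd.DataFrame,
    y,
    forced: Sequence[str] = FORCED_DEFAULT,
    cfg: GAConfig | None = None,
) -> GAResult:
    """Select descriptor columns by a seeded generational genetic algorithm.

    Chromosomes are bit-strings over the free candidate columns, repaired
    to at most ``cfg.max_free`` ones; fitness is the internal validation
    statistic of the OLS fit on forced + selected columns.  Tournament
    selection (size 3), one-point crossover, bit-flip mutation, one elite.
    Deterministic given the seed.
    """
    cfg = cfg if cfg is not None else GAConfig(seed=0)
    forced = tuple(forced)
    free = [c for c in candidates.columns if c not in forced]
    if not free:
        raise FitError("no candidate descriptor columns beyond the forced set")
    rng = np.random.default_rng(cfg.seed)
    yv = np.asarray(y, dtype=float)
    n_free = len(free)
    cache: dict[frozenset, float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = frozenset(np.flatnonzero(bits))
        if key not in cache:
            cols = forced + tuple(free[i] for i in sorted(key))
            cache[key] = _ga_fitness(candidates, yv, cols, cfg.fitness)
        return cache[key]

    def repair(bits: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(bits)
        if len(on) > cfg.max_free:
            drop = rng.choice(on, size=len(on) - cfg.max_free, replace=False)
            bits = bits.copy()
            bits[drop] = 0
        return bits

    pop = np.zeros((cfg.population, n_free), dtype=np.int8)
    for i in range(cfg.population):  # one random descriptor per individual
        pop[i, rng.integers(n_free)] = 1
    fitness = np.array([evaluate(ind) for ind in pop])
    history = [float(fitness.max())]

    for _ in range(cfg.generations):
        elite = pop[int(np.argmax(fitness))].copy()
        new_pop = [elite]
        while len(new_pop) < cfg.population:
            # tournament selection, size 3
            parents = []
            for _ in range(2):
                contenders = rng.integers(cfg.population, size=3)
                parents.append(pop[contenders[np.argmax(fitness[contenders])]].copy())
            child = parents[0]
            if rng.random() < cfg.crossover_rate and n_free > 1:
                cut = int(rng.integers(1, n_free))
                child = np.concatenate([parents[0][:cut], parents[1][cut:]])
            flips = rng.random(n_free) < cfg.mutation_rate
            child = np.where(flips, 1 - child, child).astype(np.int8)
            new_pop.append(repair(child))
        pop = np.array(new_pop)
        fitness = np.array([evaluate(ind) for ind in pop])
        history.append(float(fitness.max()))

    best = pop[int(np.argmax(fitness))]
    selected = tuple(free[i] for i in np.flatnonzero(best))
    cols = forced + selected
    fit = fit_ols(candidates[list(cols)], yv)
    return GAResult(selected, forced, fit, float(fitness.max()), history)
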
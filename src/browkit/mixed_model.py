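"""Factorial mixed-effects model for per-video eyebrow position.

The model regresses a per-video outcome (mean internal or external eyebrow
distance, pixels) on the full emotion x sentence-type x group factorial,
with crossed random effects: by-sentence intercepts and slopes for emotion,
group and their interaction, and by-signer intercepts and slopes for
emotion, sentence type and their interaction.

Categorical factors enter through difference/Helmert-style contrasts so each
coefficient is a named comparison in pixels:

* emotion:   c1 = neutral - anger,  c2 = surprise - mean(neutral, anger)
* sentence:  c1 = wh - statement,   c2 = polar - mean(statement, wh)
* group:     deaf - hearing (sum-to-zero, +1/2 / -1/2 coding)

Estimation is restricted maximum likelihood over independent variance
components (one variance per random-effect column, the ``||`` structure of
lme4), profiled down to the per-component relative variances and solved in
the low-dimensional random-effect basis.  With a small number of grouping
levels the unpenalized REML solution frequently sits on the boundary
(a singular covariance estimate); a weak Gamma(1.5, rate 0.01) penalty on
each relative variance keeps the estimate interior while perturbing
well-identified components negligibly.  Term significance is assessed by
Wald chi-square tests on the fitted coefficient covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .keypoints_io import EMOTIONS, GROUPS, SENTENCE_TYPES

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Mixed-model estimation failed after all fallbacks."""


def _coding_from_hypotheses(levels: Sequence[str], rows: np.ndarray) -> pd.DataFrame:
    """Build a contrast coding whose coefficients equal the stated comparisons.

    ``rows`` are the desired comparisons as weights over levels (one row per
    contrast); the coding matrix is the corresponding columns of the inverse
    of the full hypothesis matrix (intercept row of equal weights prepended).
    """
    k = len(levels)
    full = np.vstack([np.full(k, 1.0 / k), rows])
    coding = np.linalg.inv(full)[:, 1:]
    return pd.DataFrame(coding, index=list(levels))


@dataclass(frozen=True)
class ContrastScheme:
    """Contrast codings for the three experimental factors."""

    emotion_levels: tuple[str, ...] = EMOTIONS
    sentence_levels: tuple[str, ...] = SENTENCE_TYPES
    group_levels: tuple[str, ...] = GROUPS

    @property
    def emotion_coding(self) -> pd.DataFrame:
        # c1: neutral - anger; c2: surprise - mean(neutral, anger)
        rows = np.array([[1.0, -1.0, 0.0], [-0.5, -0.5, 1.0]])
        df = _coding_from_hypotheses(self.emotion_levels, rows)
        df.columns = ["emotion_c1", "emotion_c2"]
        return df

    @property
    def sentence_coding(self) -> pd.DataFrame:
        # c1: wh - statement; c2: polar - mean(statement, wh)
        rows = np.array([[-1.0, 0.0, 1.0], [-0.5, 1.0, -0.5]])
        df = _coding_from_hypotheses(self.sentence_levels, rows)
        df.columns = ["stype_c1", "stype_c2"]
        return df

    @property
    def group_coding(self) -> pd.DataFrame:
        # deaf - hearing; positive coefficients mean higher values for deaf
        df = _coding_from_hypotheses(self.group_levels, np.array([[1.0, -1.0]]))
        df.columns = ["group_c1"]
        return df


#: fixed-effect terms of the full factorial, with their column names
FIXED_TERMS: dict[str, list[str]] = {
    "emotion": ["emotion_c1", "emotion_c2"],
    "sentence_type": ["stype_c1", "stype_c2"],
    "group": ["group_c1"],
    "emotion:sentence_type": [
        "emotion_c1:stype_c1",
        "emotion_c1:stype_c2",
        "emotion_c2:stype_c1",
        "emotion_c2:stype_c2",
    ],
    "emotion:group": ["emotion_c1:group_c1", "emotion_c2:group_c1"],
    "sentence_type:group": ["stype_c1:group_c1", "stype_c2:group_c1"],
    "emotion:sentence_type:group": [
        "emotion_c1:stype_c1:group_c1",
        "emotion_c1:stype_c2:group_c1",
        "emotion_c2:stype_c1:group_c1",
        "emotion_c2:stype_c2:group_c1",
    ],
}

FIXED_COLUMNS = ["Intercept"] + [c for cols in FIXED_TERMS.values() for c in cols]

#: random-effect structure: grouping factor -> effect columns with slopes
RANDOM_STRUCTURE: dict[str, list[str]] = {
    # by-sentence: intercept + emotion, group and emotion:group slopes
    "sentence_id": [
        "Intercept",
        "emotion_c1",
        "emotion_c2",
        "group_c1",
        "emotion_c1:group_c1",
        "emotion_c2:group_c1",
    ],
    # by-signer: intercept + emotion, sentence-type and their interaction slopes
    "signer_id": [
        "Intercept",
        "emotion_c1",
        "emotion_c2",
        "stype_c1",
        "stype_c2",
        "emotion_c1:stype_c1",
        "emotion_c1:stype_c2",
        "emotion_c2:stype_c1",
        "emotion_c2:stype_c2",
    ],
}

#: slope groups removed, in order, when the optimizer fails outright
FALLBACK_LADDER = [
    ("signer_id", ["emotion_c1:stype_c1", "emotion_c1:stype_c2",
                   "emotion_c2:stype_c1", "emotion_c2:stype_c2"]),
    ("sentence_id", ["emotion_c1:group_c1", "emotion_c2:group_c1"]),
    ("signer_id", ["emotion_c1", "emotion_c2", "stype_c1", "stype_c2"]),
    ("sentence_id", ["emotion_c1", "emotion_c2", "group_c1"]),
]

#: a relative variance below this is reported as a singular (boundary) fit
SINGULAR_TOL = 1e-4

#: weak Gamma prior on relative variances: shape, rate
PENALTY_SHAPE = 1.5
PENALTY_RATE = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome column, contrasts, regularization, test type."""

    outcome: str = "mean_internal"
    contrast_scheme: ContrastScheme = field(default_factory=ContrastScheme)
    regularize_covariance: bool = True
    anova_type: str = "II"

    def __post_init__(self) -> None:
        if self.anova_type not in ("II", "III"):
            raise ValueError("anova_type must be 'II' or 'III'")


def build_design(table: pd.DataFrame, scheme: ContrastScheme | None = None) -> pd.DataFrame:
    """Fixed-effect design matrix (18 named columns) for a per-video table.

    Requires ``emotion``, ``sentence_type`` and ``group`` columns; raises on
    a level outside the closed label sets, naming it.
    """
    scheme = scheme or ContrastScheme()
    n = len(table)
    X = pd.DataFrame({"Intercept": np.ones(n)}, index=table.index)
    codings = {
        "emotion": scheme.emotion_coding,
        "sentence_type": scheme.sentence_coding,
        "group": scheme.group_coding,
    }
    for factor, coding in codings.items():
        vals = table[factor].astype(str)
        unknown = set(vals) - set(coding.index)
        if unknown:
            raise ValueError(f"unknown {factor} level(s): {sorted(unknown)}")
        for col in coding.columns:
            X[col] = coding[col].reindex(vals).to_numpy()
    for cols in list(FIXED_TERMS.values())[3:]:
        for name in cols:
            parts = name.split(":")
            X[name] = np.prod([X[p].to_numpy() for p in parts], axis=0)
    return X[FIXED_COLUMNS]


def _random_design(
    table: pd.DataFrame, X: pd.DataFrame, structure: dict[str, list[str]]
) -> tuple[np.ndarray, list[tuple[str, slice]]]:
    """Random-effect design Z and per-variance-component column slices.

    Each component (grouping factor x effect column) spans one column per
    level of the grouping factor, all sharing a single variance.
    """
    blocks: list[np.ndarray] = []
    comps: list[tuple[str, slice]] = []
    start = 0
    for factor, effect_cols in structure.items():
        codes, levels = pd.factorize(table[factor].astype(str), sort=True)
        ind = np.zeros((len(table), len(levels)))
        ind[np.arange(len(table)), codes] = 1.0
        for eff in effect_cols:
            block = ind * X[eff].to_numpy()[:, None]
            blocks.append(block)
            comps.append((f"{factor}|{eff}", slice(start, start + len(levels))))
            start += len(levels)
    Z = np.hstack(blocks) if blocks else np.zeros((len(table), 0))
    return Z, comps


@dataclass
class FitResult:
    """A fitted mixed model: coefficients, covariance, variance components."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: FIXED_COLUMNS; estimate, se, t
    vcov: pd.DataFrame  # coefficient covariance (p x p)
    variance_components: dict[str, float]  # absolute variances, px^2
    sigma2: float  # residual variance, px^2
    converged: bool
    singular: bool
    n_obs: int
    reml_criterion: float
    structure: dict[str, list[str]]
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _Z: np.ndarray = field(repr=False, default=None)
    _gamma: np.ndarray = field(repr=False, default=None)
    _comps: list = field(repr=False, default=None)


def _reml_pieces(
    gamma: np.ndarray,
    comps: list[tuple[str, slice]],
    ZtZ: np.ndarray,
    ZtX: np.ndarray,
    Zty: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    p: int,
):
    """Profiled REML quantities for relative variances ``gamma``.

    Marginal covariance is sigma^2 * H, H = I + Z G Z' with G diagonal per
    component; all algebra happens in the q-dimensional random-effect basis
    via the Woodbury identity.
    """
    q = ZtZ.shape[0]
    g = np.empty(q)
    for (name, sl), gk in zip(comps, gamma):
        g[sl] = gk
    sq = np.sqrt(g)
    M = np.eye(q) + (sq[:, None] * ZtZ) * sq[None, :]
    R = np.linalg.cholesky(M)
    logdet_H = 2.0 * np.sum(np.log(np.diag(R)))
    # H^-1 a = a - Zs M^-1 Zs' a  in the transformed basis
    UX = sq[:, None] * ZtX  # q x p  (= U'X with U = Z diag(sq))
    Uy = sq * Zty
    WX = np.linalg.solve(R, UX)
    Wy = np.linalg.solve(R, Uy)
    XtHiX = XtX - WX.T @ WX
    XtHiy = Xty - WX.T @ Wy
    ytHiy = yty - Wy @ Wy
    Rx = np.linalg.cholesky(XtHiX)
    beta = np.linalg.solve(Rx.T, np.linalg.solve(Rx, XtHiy))
    rss = max(ytHiy - beta @ XtHiy, 1e-12)
    sigma2 = rss / (n - p)
    logdet_XtHiX = 2.0 * np.sum(np.log(np.diag(Rx)))
    crit = (n - p) * (1.0 + math.log(2.0 * math.pi * sigma2)) + logdet_H + logdet_XtHiX
    return crit, beta, sigma2, XtHiX


def fit_mixed_model(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    structure: dict[str, list[str]] | None = None,
) -> FitResult:
    """REML fit of the factorial mixed model to a per-video summary table.

    Rows with a missing outcome are dropped.  If the optimizer fails, random
    slopes are removed in a fixed order (highest-order interactions first,
    see ``FALLBACK_LADDER``), each step logged; if every reduction fails a
    :class:`FitError` carrying optimizer diagnostics is raised.
    """
    spec = spec or ModelSpec()
    structure = structure or {k: list(v) for k, v in RANDOM_STRUCTURE.items()}
    if spec.outcome not in table.columns:
        raise ValueError(f"outcome column {spec.outcome!r} not in table")
    data = table.loc[table[spec.outcome].notna()].reset_index(drop=True)
    for factor in ("signer_id", "sentence_id"):
        if data[factor].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {factor}")
    y = data[spec.outcome].to_numpy(dtype=float)
    X = build_design(data, spec.contrast_scheme)

    diagnostics: list[str] = []
    current = {k: list(v) for k, v in structure.items()}
    ladder = iter(FALLBACK_LADDER)
    while True:
        try:
            return _fit_once(data, X, y, spec, current)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            diagnostics.append(f"{current}: {exc}")
            try:
                factor, cols = next(ladder)
            except StopIteration:
                raise FitError("mixed-model fit failed; " + " | ".join(diagnostics))
            before = list(current.get(factor, []))
            current[factor] = [c for c in before if c not in cols]
            if current[factor] == before:
                continue
            logger.warning(
                "fit failed (%s); dropping %s slopes %s and retrying", exc, factor, cols
            )


def _fit_once(
    data: pd.DataFrame,
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    structure: dict[str, list[str]],
) -> FitResult:
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    Z, comps = _random_design(data, X, structure)
    ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ Xm, Z.T @ y
    XtX, Xty, yty = Xm.T @ Xm, Xm.T @ y, float(y @ y)
    k = len(comps)

    def objective(theta: np.ndarray) -> float:
        gamma = np.exp(theta)
        crit, *_ = _reml_pieces(gamma, comps, ZtZ, ZtX, Zty, XtX, Xty, yty, n, p)
        if spec.regularize_covariance:
            # -2 log Gamma(shape, rate) prior on each relative variance
            crit += float(
                np.sum(-2.0 * (PENALTY_SHAPE - 1.0) * np.log(gamma)
                       + 2.0 * PENALTY_RATE * gamma)
            )
        return crit

    theta0 = np.full(k, math.log(0.1))
    # finite-difference step must exceed the ~1e-7 linear-algebra noise in
    # the objective; the default 1e-8 step stalls the line search
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B",
        bounds=[(-23.0, 8.0)] * k,
        options={"maxiter": 1000, "maxfun": 100_000,
                 "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-5},
    )
    # L-BFGS-B can end its line search abnormally on flat (boundary or
    # zero-residual) objectives; the best point found is still usable and
    # is reported with converged=False
    gamma = np.exp(res.x)
    crit, beta, sigma2, XtHiX = _reml_pieces(
        gamma, comps, ZtZ, ZtX, Zty, XtX, Xty, yty, n, p
    )
    if not np.isfinite(crit) or not np.all(np.isfinite(beta)):
        raise ValueError(f"optimizer diagnostics: {res.message}")
    cov_beta = sigma2 * np.linalg.inv(XtHiX)
    se = np.sqrt(np.diag(cov_beta))
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": beta / se}, index=list(X.columns)
    )
    vc = {name: float(gk * sigma2) for (name, _), gk in zip(comps, gamma)}
    singular = bool(np.any(gamma < SINGULAR_TOL))
    if singular:
        logger.info("boundary (singular) variance estimate: %s",
                    [name for (name, _), gk in zip(comps, gamma) if gk < SINGULAR_TOL])
    return FitResult(
        spec=spec,
        coefficients=coef,
        vcov=pd.DataFrame(cov_beta, index=list(X.columns), columns=list(X.columns)),
        variance_components=vc,
        sigma2=float(sigma2),
        converged=bool(res.success),
        singular=singular,
        n_obs=n,
        reml_criterion=float(crit),
        structure=structure,
        _X=Xm,
        _y=y,
        _Z=Z,
        _gamma=gamma,
        _comps=comps,
    )


def _gls_cov(fit: FitResult, cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimate and covariance for a column subset, V fixed at the fit."""
    X = fit._X[:, cols]
    Z, comps, gamma = fit._Z, fit._comps, fit._gamma
    q = Z.shape[1]
    g = np.empty(q)
    for (name, sl), gk in zip(comps, gamma):
        g[sl] = gk
    sq = np.sqrt(g)
    M = np.eye(q) + (sq[:, None] * (Z.T @ Z)) * sq[None, :]
    R = np.linalg.cholesky(M)
    UX = sq[:, None] * (Z.T @ X)
    Uy = sq * (Z.T @ fit._y)
    WX = np.linalg.solve(R, UX)
    Wy = np.linalg.solve(R, Uy)
    XtHiX = X.T @ X - WX.T @ WX
    XtHiy = X.T @ fit._y - WX.T @ Wy
    beta = np.linalg.solve(XtHiX, XtHiy)
    cov = fit.sigma2 * np.linalg.inv(XtHiX)
    return beta, cov


def anova_wald(fit: FitResult, anova_type: str | None = None) -> pd.DataFrame:
    """Wald chi-square test per fixed term.

    Type III tests each term's coefficient block against its covariance in
    the full model.  Type II tests each term in a generalized-least-squares
    refit (marginal covariance held at the fitted values) that omits every
    higher-order term containing it — the model-comparison notion of a
    Type II test in its Wald approximation.  The two coincide for the
    highest-order interaction (its conditioning set is the full model) and
    whenever the fixed-effect columns stay orthogonal under the fitted
    marginal covariance; random slopes generally break that orthogonality,
    so lower-order terms can differ between the types.
    """
    anova_type = anova_type or fit.spec.anova_type
    if anova_type not in ("II", "III"):
        raise ValueError("anova_type must be 'II' or 'III'")
    names = list(fit.coefficients.index)
    rows = []
    for term, cols in FIXED_TERMS.items():
        if any(c not in names for c in cols):
            raise ValueError(f"term {term!r} absent from the fitted model")
        if anova_type == "III":
            idx = [names.index(c) for c in cols]
            est = fit.coefficients["estimate"].to_numpy()[idx]
            cov = fit.vcov.to_numpy()[np.ix_(idx, idx)]
        else:
            factors = set(term.split(":"))
            keep = ["Intercept"] + [
                c
                for t, tc in FIXED_TERMS.items()
                if not (set(t.split(":")) > factors)
                for c in tc
            ]
            keep_idx = [names.index(c) for c in keep]
            beta, cov_all = _gls_cov(fit, keep_idx)
            pos = [keep.index(c) for c in cols]
            est = beta[pos]
            cov = cov_all[np.ix_(pos, pos)]
        chi2 = float(est @ np.linalg.solve(cov, est))
        df = len(cols)
        rows.append(
            {"term": term, "chi_square": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows).set_index("term")


#: plain-language description of each contrast coefficient, sign convention:
#: positive = higher eyebrows for the first-named side
CONTRAST_LABELS = {
    "emotion_c1": "neutral vs anger",
    "emotion_c2": "surprise vs mean(neutral, anger)",
    "stype_c1": "wh vs statement",
    "stype_c2": "polar vs mean(statement, wh)",
    "group_c1": "deaf vs hearing",
}


def report_effects(fit: FitResult) -> pd.DataFrame:
    """Readable contrast table: estimate (px), SE, t, one row per non-intercept term.

    t values beyond 1e6 (noiseless data) are flagged exact.
    """
    rows = []
    for name, row in fit.coefficients.iterrows():
        if name == "Intercept":
            continue
        label = " x ".join(CONTRAST_LABELS.get(p, p) for p in name.split(":"))
        rows.append(
            {
                "contrast": name,
                "comparison": label,
                "estimate_px": row["estimate"],
                "se": row["se"],
                "t": row["t"],
                "exact": bool(abs(row["t"]) > 1e6),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
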
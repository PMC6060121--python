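"""Fixed and mixed linear models of transformed allelic bias.

The response is a transform of the read count ratio (quasi-log Q by
default) observed on (individual, gene) cells; covariates are
biological (Dx, Age, ancestry PCs, Gender) and technical (RIN,
Institution, RNA batch).  Model structure follows the R mixed-model
formula notation::

    Q ~ RIN + (1|RNA_batch) + (Age + RIN + Ancestry.1 + Ancestry.3 | Gene)

Fixed terms are shared by all genes; each parenthesised random term is
a *batch*: a grouping factor (possibly an interaction, ``A:B``) with an
intercept and optional slope variables whose coefficients are drawn,
per level, from a common zero-mean normal with one unstructured
covariance block per batch (batches independent).  In matrix form

    y = X beta + Z b + eps,   eps ~ N(0, sigma^2 I),   b ~ N(0, Omega_b).

Estimation is maximum likelihood (never REML) so that AIC and
likelihood-ratio comparisons remain valid when models differ in fixed
or random terms.  The deviance is profiled over beta and sigma^2 and
minimised over the per-batch Cholesky factors of Omega_b / sigma^2:

    -2 l(theta) = log|Lam' Z'Z Lam + I| + n (1 + log(2 pi r^2(theta) / n)),

where Lam is the block relative-covariance factor and r^2 the minimum
of the penalised least-squares criterion |y - X beta - Z Lam u|^2 +
|u|^2.  Random coefficients are predicted as conditional means
(b = Lam u at the optimum), without confidence intervals.

Fixed (per-gene) models are ordinary or weighted least squares on the
same response; ``wnlm`` weights are proportional to the cell's total
read count T, the natural precision proxy since var(S) ~ 1/T.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomBatch", "ModelSpec", "parse_model_spec", "format_model_spec",
           "DesignMatrices", "build_design", "assemble_model_frame",
           "MixedFit", "FixedFit", "fit_mixed", "fit_fixed",
           "TermTestResult", "test_term", "add_term", "heuristic_search",
           "predict_random_coefficients", "residual_diagnostics"]


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# formula grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomBatch:
    """One random-effect batch: ``(1 + slopes | factor[:factor...])``."""

    factors: tuple[str, ...]
    slopes: tuple[str, ...] = ()

    @property
    def dim(self) -> int:
        return 1 + len(self.slopes)

    def label(self) -> str:
        lhs = " + ".join(("1",) + self.slopes)
        return f"({lhs} | {':'.join(self.factors)})"


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[str, ...] = ()
    batches: tuple[RandomBatch, ...] = ()


_TERM_SPLIT = re.compile(r"\+(?![^()]*\))")


def parse_model_spec(text: str) -> ModelSpec:
    """Parse ``response ~ fixed + (slopes|factor) + ...`` into a ModelSpec.

    The intercept is always included and may be written explicitly as
    ``1``; random terms always include a per-level intercept alongside
    any slopes (the usual R convention for ``(x|g)``).
    """
    if "~" not in text:
        raise ModelError(f"formula lacks '~': {text!r}")
    lhs, rhs = text.split("~", 1)
    response = lhs.strip()
    fixed: list[str] = []
    batches: list[RandomBatch] = []
    for raw in _TERM_SPLIT.split(rhs):
        term = raw.strip()
        if not term or term == "1":
            continue
        if term.startswith("("):
            if not term.endswith(")") or "|" not in term:
                raise ModelError(f"malformed random term: {term!r}")
            inner = term[1:-1]
            left, right = inner.split("|", 1)
            slopes = tuple(v.strip() for v in left.split("+")
                           if v.strip() and v.strip() != "1")
            factors = tuple(f.strip() for f in right.split(":") if f.strip())
            if not factors:
                raise ModelError(f"random term without grouping factor: {term!r}")
            batches.append(RandomBatch(factors=factors, slopes=slopes))
        else:
            fixed.append(term)
    return ModelSpec(response=response, fixed=tuple(fixed), batches=tuple(batches))


def format_model_spec(spec: ModelSpec) -> str:
    parts = ["1"] + list(spec.fixed) + [b.label() for b in spec.batches]
    return f"{spec.response} ~ " + " + ".join(parts)


def add_term(spec: ModelSpec, term: str) -> ModelSpec:
    """Add one term (fixed name or ``(x|F)`` text) to a model spec.

    Adding slopes for a grouping factor that already has a batch merges
    them into that batch (so testing ``(Age|Gene)`` on a model with
    ``(1|Gene)`` upgrades the gene batch to an unstructured
    intercept+slope block).  Adding a term the spec already contains
    returns the spec unchanged.
    """
    term = term.strip()
    if term.startswith("("):
        parsed = parse_model_spec(f"{spec.response} ~ {term}")
        new = parsed.batches[0]
        batches = list(spec.batches)
        for i, b in enumerate(batches):
            if b.factors == new.factors:
                slopes = b.slopes + tuple(s for s in new.slopes if s not in b.slopes)
                if slopes == b.slopes:
                    return spec
                batches[i] = RandomBatch(factors=b.factors, slopes=slopes)
                return ModelSpec(spec.response, spec.fixed, tuple(batches))
        return ModelSpec(spec.response, spec.fixed,
                         tuple(batches) + (new,))
    if term in spec.fixed or term == "1":
        return spec
    return ModelSpec(spec.response, spec.fixed + (term,), spec.batches)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    x_names: list[str]
    z_index: pd.DataFrame          # batch, level, variable per Z column
    batch_levels: list[list[str]]  # levels per batch
    batch_dims: list[int]          # 1 + #slopes per batch
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return len(self.y)


def assemble_model_frame(ratios, metadata: pd.DataFrame) -> pd.DataFrame:
    """Long model frame: one row per (individual, gene) cell with covariates."""
    frame = ratios.cells.merge(metadata, on="individual", how="left")
    frame["Gene"] = frame.gene
    frame["Individual"] = frame.individual
    return frame


def _fixed_design(data: pd.DataFrame, terms: tuple[str, ...]
                  ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in terms:
        if term not in data.columns:
            raise ModelError(f"unknown covariate {term!r}")
        col = data[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build y, dense X and sparse Z from a long model frame.

    One row per available cell (complete-case: rows with a missing
    response are dropped).  Within batch k the row's nonzero Z entries
    sit in the column block of its own group level: an intercept
    indicator followed by the slope covariate values, so batch k
    carries ``J_k = #levels * (1 + #slopes)`` columns.
    """
    if spec.response not in data.columns:
        raise ModelError(f"response {spec.response!r} not in data")
    data = data[data[spec.response].notna()].reset_index(drop=True)
    if not len(data):
        raise ModelError("no observations left after dropping missing responses")
    y = data[spec.response].to_numpy(dtype=float)
    X, x_names = _fixed_design(data, spec.fixed)

    n = len(data)
    rows, cols, vals = [], [], []
    z_cols = []
    batch_levels, batch_dims = [], []
    offset = 0
    for k, batch in enumerate(spec.batches):
        for f in batch.factors + batch.slopes:
            if f not in data.columns:
                raise ModelError(f"unknown covariate {f!r} in {batch.label()}")
        key = data[list(batch.factors)].astype(str).agg(":".join, axis=1)
        codes, levels = pd.factorize(key, sort=True)
        if len(levels) < 2:
            raise ModelError(
                f"grouping factor {':'.join(batch.factors)} has <2 levels")
        d = batch.dim
        base = offset + codes * d
        rows.append(np.arange(n))
        cols.append(base)
        vals.append(np.ones(n))
        for j, slope in enumerate(batch.slopes, start=1):
            rows.append(np.arange(n))
            cols.append(base + j)
            vals.append(data[slope].to_numpy(dtype=float))
        for lev in levels:
            for var in ("(Intercept)",) + batch.slopes:
                z_cols.append((k, lev, var))
        batch_levels.append(list(levels))
        batch_dims.append(d)
        offset += len(levels) * d
    if offset:
        Z = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, offset))
    else:
        Z = sp.csr_matrix((n, 0))
    z_index = pd.DataFrame(z_cols, columns=["batch", "level", "variable"])
    return DesignMatrices(y=y, X=X, Z=Z, x_names=x_names, z_index=z_index,
                          batch_levels=batch_levels, batch_dims=batch_dims,
                          spec=spec)


# ---------------------------------------------------------------------------
# mixed-model fitting
# ---------------------------------------------------------------------------

def _theta_slices(batch_dims: list[int]) -> list[int]:
    return [d * (d + 1) // 2 for d in batch_dims]


def _theta_bounds(batch_dims: list[int]) -> list[tuple]:
    bounds = []
    for d in batch_dims:
        for i in range(d):
            for j in range(i + 1):
                bounds.append((0.0, None) if i == j else (None, None))
    return bounds


def _cholesky_blocks(theta: np.ndarray, batch_dims: list[int]) -> list[np.ndarray]:
    blocks, pos = [], 0
    for d in batch_dims:
        C = np.zeros((d, d))
        for i in range(d):
            for j in range(i + 1):
                C[i, j] = theta[pos]
                pos += 1
        blocks.append(C)
    return blocks


def _lambda(theta: np.ndarray, design: DesignMatrices) -> sp.csr_matrix:
    parts = []
    for C, levels in zip(_cholesky_blocks(theta, design.batch_dims),
                         design.batch_levels):
        parts.append(sp.kron(sp.identity(len(levels), format="csr"),
                             sp.csr_matrix(C), format="csr"))
    return sp.block_diag(parts, format="csr") if parts else sp.csr_matrix((0, 0))


@dataclass
class MixedFit:
    spec: ModelSpec
    beta: pd.Series
    b: pd.DataFrame
    sigma2: float
    omega_blocks: list[np.ndarray]
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    theta: np.ndarray
    converged: bool
    singular: bool
    fitted: np.ndarray
    residuals: np.ndarray
    optimizer_report: dict = field(default_factory=dict)


def _profiled_deviance(theta: np.ndarray, pre: dict, design: DesignMatrices,
                       want_solution: bool = False):
    Lam = _lambda(theta, design)
    q = Lam.shape[0]
    A = (Lam.T @ pre["ZtZ"] @ Lam).toarray() + np.eye(q)
    CtZtX = Lam.T @ pre["ZtX"]
    M = np.block([[A, CtZtX], [CtZtX.T, pre["XtX"]]])
    rhs = np.concatenate([Lam.T @ pre["Zty"], pre["Xty"]])
    try:
        cM = cho_factor(M, lower=True)
        cA = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        # large finite penalty keeps finite-difference gradients usable
        return (1e12, None) if want_solution else 1e12
    gamma = cho_solve(cM, rhs)
    u, beta = gamma[:q], gamma[q:]
    resid = design.y - design.X @ beta - design.Z @ (Lam @ u)
    r2 = resid @ resid + u @ u
    n = design.n_obs
    logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
    dev = logdetA + n * (1.0 + np.log(2.0 * np.pi * r2 / n))
    if not want_solution:
        return dev
    return dev, {"beta": beta, "u": u, "Lam": Lam, "resid": resid,
                 "sigma2": r2 / n, "logdetA": logdetA}


def fit_mixed(design: DesignMatrices, tol: float = 1e-8,
              extra_starts: tuple[float, ...] = (1.0, 0.1)) -> MixedFit:
    """Maximum-likelihood fit of the mixed model described by ``design``.

    The profiled deviance is minimised with L-BFGS-B over the per-batch
    Cholesky parameters, from several starting scales (the objective is
    deterministic, so the fit is reproducible).  A variance component
    estimated at the zero boundary is flagged ``singular``, not fatal.
    With no random batches the fit reduces exactly to OLS.
    """
    X = design.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [design.x_names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ModelError(f"rank-deficient fixed design; collinear columns: {bad}")
    pre = {
        "ZtZ": (design.Z.T @ design.Z).tocsr(),
        "ZtX": design.Z.T @ X,
        "Zty": design.Z.T @ design.y,
        "XtX": X.T @ X,
        "Xty": X.T @ design.y,
    }
    n, p = design.n_obs, X.shape[1]
    n_theta = sum(_theta_slices(design.batch_dims))

    if n_theta == 0:
        beta = np.linalg.solve(pre["XtX"], pre["Xty"])
        resid = design.y - X @ beta
        sigma2 = float(resid @ resid / n)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        npar = p + 1
        return MixedFit(spec=design.spec,
                        beta=pd.Series(beta, index=design.x_names),
                        b=pd.DataFrame(columns=["batch", "level", "variable",
                                                "estimate"]),
                        sigma2=sigma2, omega_blocks=[], loglik=ll,
                        aic=-2 * ll + 2 * npar, n_params=npar, n_obs=n,
                        theta=np.zeros(0), converged=True, singular=False,
                        fitted=X @ beta, residuals=resid)

    bounds = _theta_bounds(design.batch_dims)
    starts = []
    for scale in extra_starts:
        t0 = np.zeros(n_theta)
        pos = 0
        for d in design.batch_dims:
            for i in range(d):
                for j in range(i + 1):
                    if i == j:
                        t0[pos] = scale
                    pos += 1
        starts.append(t0)

    best = None
    for t0 in starts:
        res = optimize.minimize(
            _profiled_deviance, t0, args=(pre, design), method="L-BFGS-B",
            bounds=bounds, options={"ftol": tol * 1e-4, "gtol": 1e-7,
                                    "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError(
            f"mixed-model fit failed: deviance non-finite; "
            f"message={best.message!r}, nit={best.nit}")

    theta = best.x
    dev, sol = _profiled_deviance(theta, pre, design, want_solution=True)
    ll = -0.5 * dev
    npar = p + n_theta + 1
    blocks = _cholesky_blocks(theta, design.batch_dims)
    singular = any(np.any(np.abs(np.diag(C)) < 1e-6) for C in blocks)
    omega = [sol["sigma2"] * C @ C.T for C in blocks]
    b_vec = sol["Lam"] @ sol["u"]
    b = design.z_index.copy()
    b["estimate"] = b_vec
    fitted = design.X @ sol["beta"] + design.Z @ b_vec
    return MixedFit(spec=design.spec,
                    beta=pd.Series(sol["beta"], index=design.x_names),
                    b=b, sigma2=float(sol["sigma2"]), omega_blocks=omega,
                    loglik=float(ll), aic=float(-2 * ll + 2 * npar),
                    n_params=npar, n_obs=n, theta=theta,
                    converged=bool(best.success), singular=singular,
                    fitted=fitted, residuals=design.y - fitted,
                    optimizer_report={"nit": int(best.nit),
                                      "message": str(best.message),
                                      "deviance": float(dev)})


def predict_random_coefficients(fit: MixedFit) -> pd.DataFrame:
    """Conditional-mean predictions of the random coefficients.

    One row per (batch, group level, variable).  No confidence
    intervals are attached: in a mixed model the gene-specific
    coefficients are predicted, not estimated.  When a batch's variance
    is estimated as zero all its predictions are exactly zero.
    """
    return fit.b.copy()


# ---------------------------------------------------------------------------
# fixed (per-gene) models
# ---------------------------------------------------------------------------

@dataclass
class FixedFit:
    model_class: str
    per_gene: dict

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for gene, res in self.per_gene.items():
            ci = res["conf_int"]
            for name in res["params"].index:
                rows.append({"gene": gene, "term": name,
                             "estimate": res["params"][name],
                             "se": res["bse"][name],
                             "ci_low": ci.loc[name, 0],
                             "ci_high": ci.loc[name, 1]})
        return pd.DataFrame(rows)


def fit_fixed(data: pd.DataFrame, response: str, terms: tuple[str, ...],
              model_class: str = "unlm") -> FixedFit:
    """Per-gene least-squares fits of the transformed response.

    ``unlm`` is ordinary least squares; ``wnlm`` is weighted least
    squares with weights proportional to the total read count T of each
    cell.  Genes with fewer observations than parameters are skipped
    with a warning.
    """
    import statsmodels.api as sm

    if model_class not in ("unlm", "wnlm"):
        raise ModelError(f"unknown model class {model_class!r}")
    out = {}
    for gene, sub in data.groupby("gene", observed=True):
        sub = sub[sub[response].notna()]
        X, names = _fixed_design(sub, terms)
        if len(sub) <= X.shape[1]:
            warnings.warn(f"gene {gene}: too few observations, skipped")
            continue
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ModelError(f"gene {gene}: rank-deficient design ({names})")
        y = sub[response].to_numpy(dtype=float)
        if model_class == "wnlm":
            model = sm.WLS(y, X, weights=sub["T"].to_numpy(dtype=float))
        else:
            model = sm.OLS(y, X)
        res = model.fit()
        out[gene] = {
            "params": pd.Series(res.params, index=names),
            "bse": pd.Series(res.bse, index=names),
            "conf_int": pd.DataFrame(res.conf_int(), index=names),
            "resid": res.resid,
            "fitted": res.fittedvalues,
        }
    return FixedFit(model_class=model_class, per_gene=out)


# ---------------------------------------------------------------------------
# term tests and model search
# ---------------------------------------------------------------------------

@dataclass
class TermTestResult:
    term: str
    delta_aic: float
    chi2: float
    df: int
    p_value: float
    aic_without: float
    aic_with: float


def test_term(data: pd.DataFrame, base_spec: ModelSpec, term: str
              ) -> TermTestResult:
    """Likelihood-ratio / AIC test of one term added to the base model.

    Fits the model with and without the term (all other terms kept),
    and reports delta_aic = AIC(with) - AIC(without), the chi-square
    statistic 2*(ll_with - ll_without) on df = number of extra
    parameters, and its naive chi-square p-value.  For variance
    components the true null distribution is a boundary mixture, so
    this p-value is conservative; it is reported as-is.
    """
    full_spec = add_term(base_spec, term)
    if full_spec == base_spec:
        raise ModelError(f"term {term!r} already contained in the base model")
    base = fit_mixed(build_design(data, base_spec))
    full = fit_mixed(build_design(data, full_spec))
    df = full.n_params - base.n_params
    if df < 1:
        raise ModelError(f"adding {term!r} adds no parameters (nested-model "
                         "violation)")
    chi2 = max(0.0, 2.0 * (full.loglik - base.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return TermTestResult(term=term, delta_aic=full.aic - base.aic,
                          chi2=chi2, df=df, p_value=p,
                          aic_without=base.aic, aic_with=full.aic)


def heuristic_search(data: pd.DataFrame, start_spec: ModelSpec,
                     candidate_terms: list[str]
                     ) -> tuple[ModelSpec, pd.DataFrame]:
    """Greedy forward AIC search over an ordered candidate-term list.

    Candidates are visited in order; a term is kept iff it lowers the
    AIC of the current model.  Terms already present are no-ops and
    candidates whose fit fails are skipped with a warning.  Returns the
    final spec and an audit trail of every comparison.
    """
    current = start_spec
    current_fit = fit_mixed(build_design(data, current))
    trail = []
    for term in candidate_terms:
        cand = add_term(current, term)
        if cand == current:
            trail.append({"term": term, "aic_without": current_fit.aic,
                          "aic_with": np.nan, "accepted": False,
                          "note": "already in model"})
            continue
        try:
            cand_fit = fit_mixed(build_design(data, cand))
        except (ModelError, ConvergenceError) as exc:
            warnings.warn(f"candidate {term!r} failed to fit: {exc}")
            trail.append({"term": term, "aic_without": current_fit.aic,
                          "aic_with": np.nan, "accepted": False,
                          "note": f"fit failed: {exc}"})
            continue
        accepted = cand_fit.aic < current_fit.aic
        trail.append({"term": term, "aic_without": current_fit.aic,
                      "aic_with": cand_fit.aic, "accepted": accepted,
                      "note": ""})
        if accepted:
            current, current_fit = cand, cand_fit
    return current, pd.DataFrame(trail)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(residuals: np.ndarray, fitted: np.ndarray,
                         qq_threshold: float = 0.99,
                         slope_threshold: float = 0.1) -> dict:
    """Normality and homoscedasticity summaries of a fit's residuals.

    Reports the correlation of sorted residuals with normal quantiles
    (Blom plotting positions) and the slope of |standardised residual|
    against standardised fitted values (scale-location trend).
    Constant residuals are flagged degenerate rather than crashing.
    """
    residuals = np.asarray(residuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = len(residuals)
    sd = residuals.std()
    if n < 3 or sd == 0:
        return {"qq_correlation": np.nan, "scale_location_slope": np.nan,
                "normal_ok": False, "homoscedastic_ok": False,
                "degenerate": True, "n": n}
    qnorm = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(np.sort(residuals), qnorm)[0, 1])
    fsd = fitted.std()
    if fsd == 0:
        slope = 0.0
    else:
        zf = (fitted - fitted.mean()) / fsd
        za = np.abs(residuals) / sd
        slope = float(np.polyfit(zf, za, 1)[0])
    return {"qq_correlation": qq_corr, "scale_location_slope": slope,
            "normal_ok": qq_corr >= qq_threshold,
            "homoscedastic_ok": abs(slope) <= slope_threshold,
            "degenerate": False, "n": n}
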
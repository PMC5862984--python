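"""Two-variance-component REML, likelihood-ratio tests and fast approximations.

Model: ``y = X b + g_r + g_w + e`` with ``g_r ~ N(0, K_r s2_r)``,
``g_w ~ N(0, K_w s2_w)``, ``e ~ N(0, I s2_e)``.

Estimation is average-information REML with EM fallback steps.  Every
genetic kernel is handled through a factor ``K = F F^T`` (marker loadings
for GRMs built by :mod:`hhmap.grm`, an eigenfactor otherwise), so
``V = s2_e I + sum_a s2_a F_a F_a^T`` is inverted with the Woodbury
identity and each iteration costs O(N m^2) for total factor rank m instead
of O(N^3).  The algebra is exact; no approximation is involved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .grm import RegionalGRM

logger = logging.getLogger(__name__)

__all__ = [
    "VarKernel",
    "as_kernel",
    "MixedModelSpec",
    "VarCompFit",
    "LrtResult",
    "fit_reml",
    "lrt",
    "regional_heritability",
    "grammar_residuals",
    "fast_scan_then_refit",
]

_LRT_NOISE = 1e-6  # LRT below this is convergence noise, reported as 0


class VarKernel:
    """Covariance kernel ``K = F F^T`` held as its factor ``F`` (N x m)."""

    def __init__(self, factor: np.ndarray, name: str = "kernel"):
        self.factor = np.ascontiguousarray(factor, dtype=float)
        if self.factor.ndim != 2:
            raise ValueError("kernel factor must be 2-D")
        self.name = name
        self._gram: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.factor.shape[0]

    @property
    def rank(self) -> int:
        return self.factor.shape[1]

    @property
    def gram(self) -> np.ndarray:
        """Cached F^T F (reused across fits sharing this kernel)."""
        if self._gram is None:
            self._gram = self.factor.T @ self.factor
        return self._gram

    def matrix(self) -> np.ndarray:
        return self.factor @ self.factor.T

    @classmethod
    def from_dense(cls, mat: np.ndarray, name: str = "kernel") -> "VarKernel":
        mat = np.asarray(mat, dtype=float)
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError("kernel matrix must be symmetric")
        w, u = np.linalg.eigh((mat + mat.T) / 2.0)
        tol = 1e-10 * max(1.0, float(w[-1]))
        if w[0] < -1e-6 * max(1.0, float(w[-1])):
            warnings.warn(f"kernel {name}: clipping negative eigenvalues ({w[0]:.3g})")
        keep = w > tol
        return cls(u[:, keep] * np.sqrt(w[keep]), name=name)


def as_kernel(k, name: str = "kernel") -> VarKernel:
    """Coerce a RegionalGRM / ndarray / VarKernel into a :class:`VarKernel`."""
    if isinstance(k, VarKernel):
        return k
    if isinstance(k, RegionalGRM):
        if k.loadings is not None:
            return VarKernel(k.loadings, name=name)
        _check_not_identity(k.matrix, name)
        return VarKernel.from_dense(k.matrix, name=name)
    mat = np.asarray(k, dtype=float)
    _check_not_identity(mat, name)
    return VarKernel.from_dense(mat, name=name)


def _check_not_identity(mat: np.ndarray, name: str) -> None:
    if mat.shape[0] == mat.shape[1] and np.allclose(mat, np.eye(mat.shape[0]), atol=1e-10):
        raise ValueError(
            f"component matrix equals identity ({name}): variance not identifiable "
            "against the residual"
        )


@dataclass
class MixedModelSpec:
    """Phenotype, fixed effects and the candidate variance-component kernels."""

    y: np.ndarray
    X: np.ndarray | None = None
    K_r: object = None  # RegionalGRM | ndarray | VarKernel
    K_w: object = None
    ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        else:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != n:
                raise ValueError("X rows must match y length")
        if n < self.X.shape[1] + 3:
            raise ValueError("need N >= n_fixed_effects + 3")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotypes must be finite")

    def kernel(self, component: str) -> VarKernel:
        src = {"regional": self.K_r, "whole_genome": self.K_w}[component]
        if src is None:
            raise ValueError(f"spec has no {component} matrix")
        return as_kernel(src, name=component)


@dataclass
class VarCompFit:
    """REML estimates and fit diagnostics."""

    variances: dict  # component name (incl. "residual") -> estimate
    loglik: float
    iterations: int
    converged: bool
    se: dict
    n: int
    components: tuple
    beta: np.ndarray
    _Py: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma2_r(self):
        return self.variances.get("regional")

    @property
    def sigma2_w(self):
        return self.variances.get("whole_genome")

    @property
    def sigma2_e(self):
        return self.variances["residual"]

    def to_report(self) -> dict:
        return {
            "variances": {k: float(v) for k, v in self.variances.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "n": int(self.n),
        }


@dataclass
class LrtResult:
    value: float
    significant: bool | None = None


# ---------------------------------------------------------------------------
# core REML machinery
# ---------------------------------------------------------------------------


class _WoodburyREML:
    """Restricted-likelihood evaluations for V = s2_e I + sum s2_a F_a F_a^T."""

    def __init__(self, y: np.ndarray, X: np.ndarray, kernels: list[VarKernel]):
        self.y = y
        self.X = X
        self.kernels = kernels
        self.n, self.p = X.shape
        # cross-Gram blocks are iteration-invariant
        self.FF = [[ka.factor.T @ kb.factor for kb in kernels] for ka in kernels]
        for i, k in enumerate(kernels):
            self.FF[i][i] = k.gram
        self.FX = [k.factor.T @ X for k in kernels]
        self.Fy = [k.factor.T @ y for k in kernels]

    def _solve_parts(self, theta: np.ndarray):
        """Cholesky of the Woodbury capacitance at parameters theta.

        theta = (s2 for each kernel..., s2_e).
        """
        s2e = theta[-1]
        scales = np.sqrt(theta[:-1])
        m = sum(k.rank for k in self.kernels)
        if m:
            C = np.empty((m, m))
            off = np.cumsum([0] + [k.rank for k in self.kernels])
            for i in range(len(self.kernels)):
                for j in range(len(self.kernels)):
                    blk = self.FF[i][j] if i <= j else self.FF[j][i].T
                    C[off[i]:off[i + 1], off[j]:off[j + 1]] = scales[i] * scales[j] * blk
            M = C / s2e + np.eye(m)
            L = cho_factor(M, lower=True)
            logdetM = 2.0 * np.log(np.diag(L[0])).sum()
            G = np.hstack([s * k.factor for s, k in zip(scales, self.kernels)]) if m else None
        else:
            C = np.zeros((0, 0))
            L = None
            logdetM = 0.0
            G = None
        return s2e, G, C, L, logdetM

    @staticmethod
    def _vinv(s2e, G, L, v):
        if G is None:
            return v / s2e
        gv = G.T @ v
        return (v - G @ cho_solve(L, gv) / s2e) / s2e

    def evaluate(self, theta: np.ndarray, derivs: bool = True):
        s2e, G, C, L, logdetM = self._solve_parts(theta)
        ViX = self._vinv(s2e, G, L, self.X)
        Viy = self._vinv(s2e, G, L, self.y)
        XtViX = self.X.T @ ViX
        cX = cho_factor(XtViX, lower=True)
        XtViy = self.X.T @ Viy
        beta = cho_solve(cX, XtViy)
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        logdetV = self.n * np.log(s2e) + logdetM
        logdetXtViX = 2.0 * np.log(np.diag(cX[0])).sum()
        ll = -0.5 * (
            logdetV + logdetXtViX + yPy + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        out = {"ll": float(ll), "Py": Py, "beta": beta, "s2e": s2e}
        if not derivs:
            return out

        nk = len(self.kernels)
        trPK = np.empty(nk + 1)
        quad = np.empty(nk + 1)
        wvecs = []
        off = np.cumsum([0] + [k.rank for k in self.kernels])
        scales = np.sqrt(theta[:-1])
        Minv_C = cho_solve(L, C) if L is not None else None
        for a, ka in enumerate(self.kernels):
            # tr(V^-1 K_a) via Gram algebra
            FaG = np.hstack(
                [scales[b] * (self.FF[a][b] if a <= b else self.FF[b][a].T) for b in range(nk)]
            )
            FaViFa = (self.FF[a][a] - FaG @ cho_solve(L, FaG.T) / s2e) / s2e
            XtViFa = (self.FX[a].T - (self.X.T @ G) @ cho_solve(L, FaG.T) / s2e) / s2e
            W = cho_solve(cX, XtViFa)
            trPK[a] = np.trace(FaViFa) - float(np.sum(XtViFa * W))
            w = ka.factor @ (ka.factor.T @ Py)
            wvecs.append(w)
            quad[a] = float(Py @ w)
        trVinv = (self.n - np.trace(Minv_C) / s2e) / s2e if L is not None else self.n / s2e
        XtVi2X = ViX.T @ ViX
        trPK[nk] = trVinv - float(np.trace(cho_solve(cX, XtVi2X)))
        quad[nk] = float(Py @ Py)
        wvecs.append(Py)

        score = -0.5 * (trPK - quad)
        Pw = np.column_stack(
            [self._vinv(s2e, G, L, w) - ViX @ cho_solve(cX, self.X.T @ self._vinv(s2e, G, L, w))
             for w in wvecs]
        )
        Wmat = np.column_stack(wvecs)
        AI = 0.5 * (Wmat.T @ Pw)
        out.update(score=score, AI=AI, trPK=trPK, quad=quad)
        return out


def _closed_form_residual_fit(y: np.ndarray, X: np.ndarray) -> VarCompFit:
    """Residual-only model: REML sigma2_e = RSS / (n - p), closed form."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        n * np.log(s2) + (logdetXtX - p * np.log(s2)) + rss / s2
        + (n - p) * np.log(2.0 * np.pi)
    )
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return VarCompFit(
        variances={"residual": s2},
        loglik=float(ll),
        iterations=1,
        converged=True,
        se={"residual": float(s2 * np.sqrt(2.0 / (n - p)))},
        n=n,
        components=(),
        beta=beta,
        _Py=resid / s2,
    )


def fit_reml(
    spec: MixedModelSpec,
    components: tuple = ("regional", "whole_genome"),
    max_iter: int = 200,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    max_var_mult: float | None = 1.0,
) -> VarCompFit:
    """Fit the variance-component model by AI-REML with EM fallback.

    ``components`` selects which genetic kernels enter the model; the
    residual variance is always included.  Negative proposals are projected
    to a small floor (1e-8 x var(y)); estimates still at the floor on exit
    are reported as 0.  Following the GCTA-family convention, every
    component is constrained to at most ``max_var_mult * var(y)`` (pass
    ``None`` for unconstrained estimation).
    """
    components = tuple(components)
    y, X = spec.y, spec.X
    if not components:
        return _closed_form_residual_fit(y, X)
    kernels = [spec.kernel(c) for c in components]
    for k, c in zip(kernels, components):
        if k.n != y.size:
            raise ValueError(f"{c} kernel size does not match phenotype length")

    engine = _WoodburyREML(y, X, kernels)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    cap = np.inf if max_var_mult is None else max_var_mult * vary
    nk = len(kernels)
    theta = np.empty(nk + 1)
    theta[-1] = 0.5 * vary
    theta[:-1] = 0.5 * vary / nk

    def _clip(th):
        return np.clip(th, floor, cap)

    def em_step(th, ev):
        return _clip(th + (th**2 / engine.n) * (ev["quad"] - ev["trPK"]))

    ev = engine.evaluate(theta)
    if not np.isfinite(ev["ll"]):
        raise FloatingPointError("non-finite restricted likelihood at start")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            cand = em_step(theta, ev)
        else:
            cand = None
            try:
                delta = np.linalg.solve(ev["AI"], ev["score"])
                trial = _clip(theta + delta)
                for _ in range(9):
                    ev_t = engine.evaluate(trial, derivs=False)
                    if np.isfinite(ev_t["ll"]) and ev_t["ll"] >= ev["ll"] - 1e-10:
                        cand = trial
                        break
                    trial = _clip(theta + (trial - theta) / 2.0)
            except np.linalg.LinAlgError:
                pass
            if cand is None:
                cand = em_step(theta, ev)
        ev_new = engine.evaluate(cand)
        if not np.isfinite(ev_new["ll"]):
            raise FloatingPointError("non-finite restricted likelihood during iteration")
        dll = abs(ev_new["ll"] - ev["ll"])
        dpar = np.max(np.abs(cand - theta)) / vary
        theta, ev = cand, ev_new
        if dll < tol_ll * max(1.0, abs(ev["ll"])) or dpar < tol_par:
            converged = True
            break
    if not converged:
        warnings.warn("REML did not converge within max_iter", RuntimeWarning)

    try:
        ai_inv = np.linalg.inv(ev["AI"])
        se_vals = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except np.linalg.LinAlgError:
        se_vals = np.full(nk + 1, np.nan)
    names = list(components) + ["residual"]
    variances = {
        nm: (0.0 if v <= floor * (1 + 1e-9) and nm != "residual" else float(v))
        for nm, v in zip(names, theta)
    }
    return VarCompFit(
        variances=variances,
        loglik=float(ev["ll"]),
        iterations=it,
        converged=converged,
        se=dict(zip(names, se_vals)),
        n=engine.n,
        components=components,
        beta=ev["beta"],
        _Py=ev["Py"],
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def lrt(full: VarCompFit, null: VarCompFit, threshold: float | None = None) -> LrtResult:
    """Likelihood-ratio test of the regional component, floored at zero."""
    extra = set(full.components) - set(null.components)
    if extra != {"regional"} or full.n != null.n:
        raise ValueError("null model must be the full spec without the regional component")
    value = 2.0 * (full.loglik - null.loglik)
    value = 0.0 if value < _LRT_NOISE else float(value)
    return LrtResult(value, None if threshold is None else value >= threshold)


def regional_heritability(fit: VarCompFit) -> float:
    """RH = s2_r / (s2_r + s2_w + s2_e)."""
    for name in ("regional", "whole_genome", "residual"):
        if name not in fit.variances:
            raise ValueError(f"fit lacks the {name} component")
    total = sum(fit.variances.values())
    if total <= 0:
        raise ValueError("zero total variance")
    return float(fit.variances["regional"] / total)


def grammar_residuals(spec: MixedModelSpec) -> np.ndarray:
    """Phenotype pre-adjusted for fixed effects and the whole-genome BLUP.

    Fits the null (whole-genome + residual) model and returns
    ``y - X beta - g_w_hat = s2_e * P y``, which has exactly zero mean when X
    contains an intercept.
    """
    null = fit_reml(spec, components=("whole_genome",))
    if not null.converged:
        raise RuntimeError("null model did not converge; cannot form residuals")
    return null.variances["residual"] * null._Py


def fast_scan_then_refit(
    y: np.ndarray,
    X: np.ndarray | None,
    K_w,
    window_kernels: list,
    top_fraction: float = 0.1,
) -> list[dict]:
    """Two-pass scan: regional-only fits first, full refit of the top windows.

    Pass 1 fits regional + residual per window (no whole-genome component)
    and computes an approximate LRT against the residual-only model.  The
    top ``ceil(top_fraction * W)`` windows by pass-1 LRT are refitted with
    the full two-component model; the rest keep pass-1 numbers flagged
    ``approximate``.
    """
    if not window_kernels:
        raise ValueError("empty window list")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    records = []
    for idx, kern in enumerate(window_kernels):
        spec1 = MixedModelSpec(y=y, X=X, K_r=kern)
        full1 = fit_reml(spec1, components=("regional",))
        null1 = _closed_form_residual_fit(spec1.y, spec1.X)
        stat = lrt(full1, null1)
        v = full1.variances
        records.append(
            {
                "window": idx,
                "lrt": stat.value,
                "rh": v["regional"] / (v["regional"] + v["residual"]),
                "sigma2_r": v["regional"],
                "sigma2_w": np.nan,
                "sigma2_e": v["residual"],
                "approximate": True,
            }
        )
    n_top = max(1, int(np.ceil(top_fraction * len(window_kernels))))
    top = sorted(records, key=lambda r: r["lrt"], reverse=True)[:n_top]
    null_spec = MixedModelSpec(y=y, X=X, K_w=K_w)
    null_full = fit_reml(null_spec, components=("whole_genome",))
    for rec in top:
        kern = window_kernels[rec["window"]]
        spec = MixedModelSpec(y=y, X=X, K_r=kern, K_w=K_w)
        full = fit_reml(spec)
        rec.update(
            lrt=lrt(full, null_full).value,
            rh=regional_heritability(full),
            sigma2_r=full.variances["regional"],
            sigma2_w=full.variances["whole_genome"],
            sigma2_e=full.variances["residual"],
            approximate=False,
        )
    return records
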
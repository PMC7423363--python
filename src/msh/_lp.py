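"""Small linear-programming layer used by the FBA solver.

Two interchangeable backends solve ``max c.v  s.t.  A v = 0,  lb <= v <= ub``:

* ``glpk`` -- a persistent GLPK problem (via :mod:`swiglpk`) whose column
  bounds are updated in place between solves.  Warm-started simplex restarts
  cost microseconds, which is what makes time-stepped community FBA over a
  full stability grid tractable.
* ``scipy`` -- :func:`scipy.optimize.linprog` (HiGHS), rebuilt per call.
  Slower but dependency-free; both backends return the same optimum.

The backend is chosen automatically at import time.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

try:  # pragma: no cover - exercised implicitly by backend selection
    import swiglpk as _glp

    HAVE_GLPK = True
except Exception:  # pragma: no cover
    _glp = None
    HAVE_GLPK = False

#: solver status values normalised across backends
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"


def _as_coo(A) -> sp.coo_matrix:
    return sp.coo_matrix(A)


class _GlpkLP:
    """Persistent GLPK problem over a fixed constraint matrix."""

    def __init__(self, A, c, maximize: bool = True):
        A = _as_coo(A)
        m, n = A.shape
        self.m, self.n = m, n
        lp = _glp.glp_create_prob()
        _glp.glp_set_obj_dir(lp, _glp.GLP_MAX if maximize else _glp.GLP_MIN)
        _glp.glp_add_rows(lp, m)
        for i in range(m):
            _glp.glp_set_row_bnds(lp, i + 1, _glp.GLP_FX, 0.0, 0.0)
        _glp.glp_add_cols(lp, n)
        for j, cj in enumerate(np.asarray(c, dtype=float)):
            _glp.glp_set_obj_coef(lp, j + 1, float(cj))
        nz = A.nnz
        ia = _glp.intArray(nz + 1)
        ja = _glp.intArray(nz + 1)
        ar = _glp.doubleArray(nz + 1)
        for k, (i, j, v) in enumerate(zip(A.row, A.col, A.data), start=1):
            ia[k] = int(i) + 1
            ja[k] = int(j) + 1
            ar[k] = float(v)
        _glp.glp_load_matrix(lp, nz, ia, ja, ar)
        parm = _glp.glp_smcp()
        _glp.glp_init_smcp(parm)
        parm.msg_lev = _glp.GLP_MSG_OFF
        self._lp = lp
        self._parm = parm
        self._warm = False

    def set_row_lower(self, i: int, lower: float) -> None:
        """Constrain row ``i`` (0-based) to ``>= lower`` instead of == 0."""
        _glp.glp_set_row_bnds(self._lp, i + 1, _glp.GLP_LO, float(lower), 0.0)

    def solve(self, lb: np.ndarray, ub: np.ndarray):
        lp = self._lp
        for j in range(self.n):
            lo, hi = float(lb[j]), float(ub[j])
            if lo == hi:
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_FX, lo, hi)
            else:
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_DB, lo, hi)
        ret = _glp.glp_simplex(lp, self._parm)
        status = _glp.glp_get_status(lp)
        if ret != 0 or status == _glp.GLP_UNDEF:
            # warm basis occasionally goes stale after large bound moves
            _glp.glp_std_basis(lp)
            ret = _glp.glp_simplex(lp, self._parm)
            status = _glp.glp_get_status(lp)
        if ret != 0:
            return FAILED, np.nan, None
        if status == _glp.GLP_OPT:
            x = np.fromiter(
                (_glp.glp_get_col_prim(lp, j + 1) for j in range(self.n)),
                dtype=float,
                count=self.n,
            )
            return OPTIMAL, _glp.glp_get_obj_val(lp), x
        if status in (_glp.GLP_INFEAS, _glp.GLP_NOFEAS):
            return INFEASIBLE, np.nan, None
        if status == _glp.GLP_UNBND:
            return UNBOUNDED, np.inf, None
        return FAILED, np.nan, None

    def __del__(self):  # pragma: no cover
        try:
            _glp.glp_delete_prob(self._lp)
        except Exception:
            pass


class _ScipyLP:
    """linprog/HiGHS fallback with the same interface as :class:`_GlpkLP`."""

    def __init__(self, A, c, maximize: bool = True):
        from scipy.optimize import linprog  # deferred; hot path uses glpk

        self._linprog = linprog
        self._A = sp.csr_matrix(A)
        self.m, self.n = self._A.shape
        self._c = np.asarray(c, dtype=float)
        self._sign = -1.0 if maximize else 1.0
        self._row_lower: dict[int, float] = {}

    def set_row_lower(self, i: int, lower: float) -> None:
        self._row_lower[i] = float(lower)

    def solve(self, lb, ub):
        b_lo = np.zeros(self.m)
        b_hi = np.zeros(self.m)
        for i, lo in self._row_lower.items():
            b_lo[i] = lo
            b_hi[i] = np.inf
        res = self._linprog(
            self._sign * self._c,
            A_ub=sp.vstack([self._A, -self._A]) if self._row_lower else None,
            b_ub=np.concatenate([b_hi, -b_lo]) if self._row_lower else None,
            A_eq=None if self._row_lower else self._A,
            b_eq=None if self._row_lower else np.zeros(self.m),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 0:
            return OPTIMAL, self._sign * res.fun, res.x
        if res.status == 2:
            return INFEASIBLE, np.nan, None
        if res.status == 3:
            return UNBOUNDED, np.inf, None
        return FAILED, np.nan, None


def make_lp(A, c, maximize: bool = True, backend: str = "auto"):
    """Create a persistent LP for the given constraint matrix and objective."""
    if backend == "auto":
        backend = "glpk" if HAVE_GLPK else "scipy"
    if backend == "glpk":
        if not HAVE_GLPK:
            raise RuntimeError("GLPK backend requested but swiglpk is unavailable")
        return _GlpkLP(A, c, maximize)
    if backend == "scipy":
        return _ScipyLP(A, c, maximize)
    raise ValueError(f"unknown LP backend {backend!r}")
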
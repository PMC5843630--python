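"""IPS-family electrostatic pair potentials and their cut-off boundary conditions.

The isotropic periodic sum (IPS) replaces the long-range tail of the Coulomb
interaction with the analytic effect of isotropically distributed periodic
images inside a local sphere of radius ``r_c``: the pair energy becomes

    u(r) = 1/r + phi(r; r_c)        for r <= r_c,   u(r) = 0 beyond,

where the image term ``phi`` is an even polynomial in the reduced distance
``s = r/r_c``, scaled by ``1/r_c``. The members of the family differ only in
which derivative orders of the total pair function are forced to vanish at
the cut-off boundary:

* ``IPSn``  — energy and first derivative vanish at ``r_c`` (the variant
  designed for non-polar systems; equivalent to the conducting reaction
  field form ``1/r + r^2/(2 r_c^3) - 3/(2 r_c)``),
* ``IPSp``  — orders 0..3 vanish (the polar variant, whose counter-charge
  assumption at the boundary removes the 2nd and 3rd derivatives),
* ``LIPS5th`` — orders 0..5 vanish,
* ``LIPSSW`` — orders 0..5 vanish, with one extra basis degree fixed by a
  reaction-field-like curvature condition at the origin (the ``s^2``
  coefficient matches the conducting reaction field value 1/2).

Coefficients are obtained by solving the linear system these conditions
impose on the polynomial basis, so alternative published coefficient sets
can be dropped in by constructing :class:`IpsPotential` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

from .constants import CONSTANTS
from .model import WaterModel, SPCE


def _falling_factorial(n: int, m: int) -> float:
    """n (n-1) ... (n-m+1); equals 1 for m = 0."""
    out = 1.0
    for i in range(m):
        out *= n - i
    return out


@dataclass(frozen=True)
class BoundaryConditionSpec:
    """Which derivative orders of u(r) vanish at r_c, and the basis size.

    ``basis_degree`` is the highest (even) power of ``s = r/r_c`` in the
    image-term polynomial. ``sq_coefficient`` optionally pins the reduced
    ``s^2`` coefficient (used by LIPS-SW's reaction-field-like condition).
    """

    method_id: str
    vanish_orders: tuple = (0, 1)
    basis_degree: int = 2
    sq_coefficient: float | None = None

    def __post_init__(self) -> None:
        orders = tuple(self.vanish_orders)
        if len(orders) == 0:
            raise ValueError("vanish_orders must be non-empty")
        if 0 not in orders:
            raise ValueError("vanish_orders must include 0 (energy continuity)")
        if list(orders) != sorted(orders):
            raise ValueError("vanish_orders must be sorted")
        if self.basis_degree % 2 != 0:
            raise ValueError("basis_degree must be even")
        if self.basis_degree < max(orders):
            raise ValueError(
                f"basis_degree {self.basis_degree} too small for derivative "
                f"orders {orders}: need at least {max(orders)}"
            )
        object.__setattr__(self, "vanish_orders", orders)

    @property
    def n_basis(self) -> int:
        return self.basis_degree // 2 + 1

    @property
    def n_conditions(self) -> int:
        return len(self.vanish_orders) + (self.sq_coefficient is not None)


#: Boundary-condition specifications of the four implemented methods.
METHOD_SPECS: dict[str, BoundaryConditionSpec] = {
    "IPSn": BoundaryConditionSpec("IPSn", (0, 1), 2),
    "IPSp": BoundaryConditionSpec("IPSp", (0, 1, 2, 3), 6),
    "LIPS5th": BoundaryConditionSpec("LIPS5th", (0, 1, 2, 3, 4, 5), 10),
    "LIPSSW": BoundaryConditionSpec(
        "LIPSSW", (0, 1, 2, 3, 4, 5), 12, sq_coefficient=0.5
    ),
}


@dataclass
class IpsPotential:
    """A solved IPS pair potential: 1/r plus an even-polynomial image term.

    ``reduced_coefficients[k]`` multiplies ``s^(2k)`` in
    ``phi(r) = (1/r_c) * sum_k c_k (r/r_c)^(2k)``; they are dimensionless
    and independent of ``r_c``.
    """

    method_id: str
    r_c: float
    reduced_coefficients: np.ndarray
    spec: BoundaryConditionSpec | None = None

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        self.reduced_coefficients = np.asarray(self.reduced_coefficients, float)

    def image_term(self, r) -> np.ndarray:
        """phi(r; r_c), the IPS image correction (per unit coulomb_factor*qq)."""
        s2 = np.square(np.asarray(r, float) / self.r_c)
        c = self.reduced_coefficients
        out = np.full_like(s2, c[-1])
        for ck in c[-2::-1]:
            out = out * s2 + ck
        return out / self.r_c

    def total_derivative(self, r, order: int = 0) -> np.ndarray:
        """d^order/dr^order of the smooth branch u(r) = 1/r + phi(r).

        Evaluated analytically (term-wise), not by finite differences, so it
        is reliable at high orders where difference stencils lose precision.
        """
        r = np.asarray(r, float)
        out = (-1.0) ** order * math.factorial(order) / r ** (order + 1)
        for k, ck in enumerate(self.reduced_coefficients):
            ff = _falling_factorial(2 * k, order)
            if ff != 0.0:
                out = out + ck * ff * r ** (2 * k - order) / self.r_c ** (2 * k + 1)
        return out

    def kernel(self, r) -> np.ndarray:
        """Truncated electrostatic kernel u(r): 1/r + phi for r <= r_c, else 0."""
        r = np.asarray(r, float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        inside = r <= self.r_c
        ri = r[inside]
        out[inside] = 1.0 / ri + self.image_term(ri)
        return float(out[0]) if scalar else out

    def kernel_derivative(self, r) -> np.ndarray:
        """du/dr of the truncated kernel (0 beyond r_c)."""
        r = np.asarray(r, float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        inside = r <= self.r_c
        out[inside] = self.total_derivative(r[inside], 1)
        return float(out[0]) if scalar else out


def solve_ips_coefficients(spec: BoundaryConditionSpec, r_c: float) -> IpsPotential:
    """Solve the cut-off boundary conditions for the image-term coefficients.

    For each order ``m`` in ``spec.vanish_orders`` the condition
    ``d^m u/dr^m (r_c) = 0`` with ``u = 1/r + (1/r_c) sum_k c_k s^(2k)``
    reduces (after multiplying by ``r_c^(m+1)``) to the dimensionless linear
    equation ``sum_k c_k (2k)(2k-1)...(2k-m+1) = (-1)^(m+1) m!``.

    Raises
    ------
    ValueError
        If the basis is too small for the number of conditions, or the
        system is singular/inconsistent (the error names the conditions
        that cannot be satisfied simultaneously).
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    nb = spec.n_basis
    rows = []
    rhs = []
    labels = []
    for m in spec.vanish_orders:
        rows.append([_falling_factorial(2 * k, m) for k in range(nb)])
        rhs.append((-1.0) ** (m + 1) * math.factorial(m))
        labels.append(f"d^{m}u/dr^{m}(r_c)=0")
    if spec.sq_coefficient is not None:
        row = [0.0] * nb
        if nb < 2:
            raise ValueError("basis_degree too small for the s^2 constraint")
        row[1] = 1.0
        rows.append(row)
        rhs.append(spec.sq_coefficient)
        labels.append(f"c_1={spec.sq_coefficient}")
    a = np.array(rows)
    b = np.array(rhs)
    if a.shape[0] > nb:
        raise ValueError(
            f"basis_degree {spec.basis_degree} too small: {a.shape[0]} conditions "
            f"but only {nb} even-polynomial coefficients"
        )
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    residual = a @ coeffs - b
    if np.max(np.abs(residual)) > 1e-9 * max(1.0, np.max(np.abs(b))):
        worst = [labels[i] for i in np.argsort(-np.abs(residual))[:2]]
        raise ValueError(
            "singular or inconsistent boundary system; conflicting conditions: "
            + ", ".join(worst)
        )
    return IpsPotential(spec.method_id, r_c, coeffs, spec=spec)


def make_potential(method_id: str, r_c: float) -> IpsPotential:
    """Convenience constructor from a registered method name."""
    try:
        spec = METHOD_SPECS[method_id]
    except KeyError:
        raise ValueError(
            f"unknown method {method_id!r}; choose from {sorted(METHOD_SPECS)}"
        ) from None
    return solve_ips_coefficients(spec, r_c)


def evaluate_pair(pot: IpsPotential, r, qq) -> tuple:
    """Electrostatic energy and scalar force of a charge pair at distance r.

    energy = coulomb_factor * qq * [1/r + phi(r)] inside the cut-off and
    exactly 0 beyond; force = -d(energy)/dr (positive force is repulsive).
    """
    r_arr = np.asarray(r, float)
    if np.any(r_arr <= 0):
        raise ValueError("pair distance must be positive")
    ke = CONSTANTS.coulomb_factor
    energy = ke * np.asarray(qq, float) * pot.kernel(r_arr)
    force = -ke * np.asarray(qq, float) * pot.kernel_derivative(r_arr)
    if np.ndim(r) == 0 and np.ndim(qq) == 0:
        return float(energy), float(force)
    return energy, force


def verify_boundary(pot: IpsPotential, max_order: int = 6, tol: float = 1e-8) -> dict:
    """Report |d^k u/dr^k| at r_c for k = 0..max_order and flag violations.

    Magnitudes are measured relative to the same derivative at r_c/2 (a
    representative interior point), so the report is scale-free. Orders in
    the potential's vanish list whose relative magnitude exceeds ``tol``
    are flagged.
    """
    report = {"method_id": pot.method_id, "r_c": pot.r_c, "orders": {}}
    vanish = pot.spec.vanish_orders if pot.spec is not None else ()
    ok = True
    for k in range(max_order + 1):
        at_rc = float(pot.total_derivative(pot.r_c, k))
        scale = abs(float(pot.total_derivative(pot.r_c / 2.0, k)))
        rel = abs(at_rc) / scale if scale > 0 else abs(at_rc)
        entry = {
            "value": at_rc,
            "relative": rel,
            "required_zero": k in vanish,
            "violation": k in vanish and rel > tol,
        }
        ok = ok and not entry["violation"]
        report["orders"][k] = entry
    report["all_conditions_met"] = ok
    return report


# ---------------------------------------------------------------------------
# Tabulated potentials (GROMACS xvg table dialect)
# ---------------------------------------------------------------------------

#: Below this grid start the 1/r^12 column overflows usefully; pair
#: distances under it are treated as hard overlaps by the cutoff engine.
TABLE_R_START = 0.002  # nm
DEFAULT_TABLE_SPACING = 0.0005  # nm


@dataclass
class PairPotentialTable:
    """Sampled pair-interaction curves in the GROMACS table convention.

    Columns: r, f(r), -f'(r), g(r), -g'(r), h(r), -h'(r), where the total
    pair energy is ``qq*coulomb_factor*f + C6*g + C12*h`` with ``g = -r^-6``
    and ``h = r^-12``. The electrostatic column is the truncated IPS kernel;
    with a pseudo cut-off ``r_c* > r_c`` the rows on ``(r_c, r_c*]`` are
    exactly zero, which makes a group-based list at radius ``r_c*``
    numerically identical to an atom-based list at ``r_c``.
    """

    r: np.ndarray
    f: np.ndarray
    minus_fprime: np.ndarray
    g: np.ndarray
    minus_gprime: np.ndarray
    h: np.ndarray
    minus_hprime: np.ndarray
    method_id: str = ""
    r_c: float = 0.0
    pseudo_r_c: float | None = None

    def __post_init__(self) -> None:
        for name in ("r", "f", "minus_fprime", "g", "minus_gprime", "h", "minus_hprime"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        dr = np.diff(self.r)
        if dr.size and not np.allclose(dr, dr[0], rtol=1e-9, atol=1e-12):
            raise ValueError("table grid must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def list_radius(self) -> float:
        """Radius a pair list must use with this table (pseudo r_c if set)."""
        return self.pseudo_r_c if self.pseudo_r_c is not None else self.r_c

    def _basis(self, r: np.ndarray):
        """Shared cubic-Hermite basis: interval index and blending weights."""
        if r.size and r.min() < self.r[0]:
            raise ValueError(
                f"pair distance {r.min():.4f} nm below table start {self.r[0]} nm "
                "(atomic overlap)"
            )
        h = self.spacing
        beyond = r > self.r[-1]
        rc = np.where(beyond, self.r[-1], r)
        idx = np.minimum(((rc - self.r[0]) / h).astype(int), len(self.r) - 2)
        t = (rc - self.r[idx]) / h
        t2 = t * t
        t3 = t2 * t
        w = (
            2 * t3 - 3 * t2 + 1,  # h00
            t3 - 2 * t2 + t,  # h10
            -2 * t3 + 3 * t2,  # h01
            t3 - t2,  # h11
            (6 * t2 - 6 * t) / h,
            (3 * t2 - 4 * t + 1) / h,
            (-6 * t2 + 6 * t) / h,
            (3 * t2 - 2 * t) / h,
        )
        return idx, w, beyond

    def _interp(self, idx, w, beyond, y: np.ndarray, yd: np.ndarray):
        """Cubic Hermite value and exact first derivative of one column."""
        h = self.spacing
        y0, y1 = y[idx], y[idx + 1]
        d0, d1 = yd[idx] * h, yd[idx + 1] * h
        val = w[0] * y0 + w[1] * d0 + w[2] * y1 + w[3] * d1
        dval = w[4] * y0 + w[5] * d0 + w[6] * y1 + w[7] * d1
        val[beyond] = 0.0
        dval[beyond] = 0.0
        return val, dval

    def evaluate_coulomb(self, r: np.ndarray):
        """Interpolated electrostatic kernel and its derivative at r."""
        r = np.asarray(r, float)
        idx, w, beyond = self._basis(r)
        return self._interp(idx, w, beyond, self.f, -self.minus_fprime)

    def evaluate_lj(self, r: np.ndarray):
        """Interpolated dispersion/repulsion columns (g, dg, h, dh) at r."""
        r = np.asarray(r, float)
        idx, w, beyond = self._basis(r)
        g, dg = self._interp(idx, w, beyond, self.g, -self.minus_gprime)
        h_, dh = self._interp(idx, w, beyond, self.h, -self.minus_hprime)
        return g, dg, h_, dh

    def evaluate(self, r: np.ndarray):
        """Interpolate all three interaction classes at distances r.

        Returns ``(f, df, g, dg, h, dh)`` where d* are first derivatives of
        the interpolants; the derivative is the exact gradient of the
        interpolated value, so tabulated forces integrate the tabulated
        energy. Distances beyond the grid give zeros; below the grid start
        raise (atomic overlap).
        """
        r = np.asarray(r, float)
        idx, w, beyond = self._basis(r)
        out = []
        for y, yd in (
            (self.f, -self.minus_fprime),
            (self.g, -self.minus_gprime),
            (self.h, -self.minus_hprime),
        ):
            out.extend(self._interp(idx, w, beyond, y, yd))
        return tuple(out)

    def to_text(self) -> str:
        pseudo = "none" if self.pseudo_r_c is None else f"{self.pseudo_r_c:.6f}"
        lines = [
            f"# ipswater table method={self.method_id} r_c={self.r_c:.6f} "
            f"pseudo_r_c={pseudo}"
        ]
        cols = np.column_stack(
            [self.r, self.f, self.minus_fprime, self.g, self.minus_gprime,
             self.h, self.minus_hprime]
        )
        for row in cols:
            lines.append(" ".join(f"{v: .12e}" for v in row))
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "PairPotentialTable":
        method_id, r_c, pseudo = "", 0.0, None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.split():
                    if tok.startswith("method="):
                        method_id = tok.split("=", 1)[1]
                    elif tok.startswith("r_c="):
                        r_c = float(tok.split("=", 1)[1])
                    elif tok.startswith("pseudo_r_c="):
                        val = tok.split("=", 1)[1]
                        pseudo = None if val == "none" else float(val)
        data = np.loadtxt(path, comments="#")
        return cls(*data.T, method_id=method_id, r_c=r_c, pseudo_r_c=pseudo)


def write_table(
    pot: IpsPotential,
    lj: WaterModel = SPCE,
    spacing: float = DEFAULT_TABLE_SPACING,
    r_max: float | None = None,
    pseudo_r_c: float | None = None,
    lj_cutoff: float | None = None,
    path=None,
) -> PairPotentialTable:
    """Tabulate an IPS potential (plus plainly truncated LJ columns).

    The LJ cut-off defaults to min(4 sigma, r_c) so that every interaction
    column is exactly zero beyond the electrostatic cut-off. Rows with
    r > r_c are zeroed exactly; with ``pseudo_r_c`` the grid extends to it,
    giving the zero-padded table the group-based scheme needs to reproduce
    atom-based truncation at r_c.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > TABLE_R_START:
        warnings.warn(
            f"table spacing {spacing} nm is coarser than {TABLE_R_START} nm; "
            "cubic interpolation error may be significant",
            stacklevel=2,
        )
    r_c = pot.r_c
    if pseudo_r_c is not None and pseudo_r_c < r_c:
        raise ValueError("pseudo_r_c must be >= r_c")
    if r_max is None:
        r_max = pseudo_r_c if pseudo_r_c is not None else r_c
    if r_max < r_c:
        raise ValueError("r_max must be >= r_c")
    if pseudo_r_c is not None and r_max < pseudo_r_c:
        raise ValueError("r_max must be >= pseudo_r_c")
    if lj_cutoff is None:
        lj_cutoff = min(4.0 * lj.sigma_oo, r_c)

    n = int(math.ceil((r_max - TABLE_R_START) / spacing)) + 1
    r = TABLE_R_START + spacing * np.arange(n + 1)

    inside = r <= r_c
    f = np.where(inside, 1.0 / r + pot.image_term(r), 0.0)
    fprime = np.where(inside, pot.total_derivative(r, 1), 0.0)

    # LJ columns are truncated and energy-shifted to zero at the LJ cut-off:
    # the shift leaves forces untouched but keeps the tabulated energy
    # continuous when pairs cross the boundary, which NVE conservation at
    # desk-scale cut-offs requires (at the production-scale LJ cut-off of
    # 4 sigma the shift is ~1e-3 kJ/mol and immaterial)
    lj_in = r <= lj_cutoff
    g = np.where(lj_in, -(r ** -6.0) + lj_cutoff ** -6.0, 0.0)
    gprime = np.where(lj_in, 6.0 * r ** -7.0, 0.0)
    h = np.where(lj_in, r ** -12.0 - lj_cutoff ** -12.0, 0.0)
    hprime = np.where(lj_in, -12.0 * r ** -13.0, 0.0)

    table = PairPotentialTable(
        r, f, -fprime, g, -gprime, h, -hprime,
        method_id=pot.method_id, r_c=r_c, pseudo_r_c=pseudo_r_c,
    )
    if path is not None:
        table.write(path)
    return table
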
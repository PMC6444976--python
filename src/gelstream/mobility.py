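"""Field- and length-dependent electrophoretic mobility of DNA in agarose.

In a sieving gel, double-stranded DNA migrates by biased reptation: the
chain threads through the pore network and progressively aligns with the
field, so its mobility mu grows with the field strength E and falls with
the contour length L.  When the field direction changes, a chain needs a
finite reorientation time t_or = L / (mu * E) to realign; the corresponding
reorientation frequency f_or = 1 / (2 * t_or) is the switching frequency
above which a fragment can no longer follow that field component.

Units are fixed package-wide: E in V/cm, mu in cm^2/(V s), lengths in cm
internally (0.34 nm per base pair of contour length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: dsDNA contour length per base pair, in cm (0.34 nm/bp).
CM_PER_BP = 0.34e-7

#: Default Kuhn-segment size in base pairs (~100 nm Kuhn length of dsDNA).
DEFAULT_KUHN_BP = 300.0

TABLE_COLUMNS = ("E_V_per_cm", "length_bp", "mobility_cm2_per_Vs")


@dataclass(frozen=True)
class FragmentSpec:
    """A DNA fragment identified by its length in base pairs."""

    length_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"length_bp must be >= 1, got {self.length_bp}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.length_bp}bp")

    @property
    def contour_length_cm(self) -> float:
        """Fully extended backbone length, length_bp * 0.34 nm, in cm."""
        return self.length_bp * CM_PER_BP


@dataclass(frozen=True)
class KineticsResult:
    """Reorientation time/frequency of one fragment at one field strength."""

    t_or_s: float
    f_or_Hz: float
    field_V_per_cm: float
    fragment: FragmentSpec


class MobilityRangeError(ValueError):
    """Query outside a calibration table's grid without extrapolation."""


class MobilityModel:
    """Mapping (E, L) -> mu with derivative access.

    Two modes:

    * ``parametric`` -- biased-reptation-style closed form
      ``mu(E, N) = mu0 * (1/(3N) + beta*E^2 / (1 + gamma*E^2))`` with
      ``N = length_bp / kuhn_bp`` the chain length in Kuhn segments.
      Non-decreasing in E and non-increasing in length by construction
      (mu0, beta, gamma >= 0).
    * ``table`` -- bilinear interpolation of measured (E, length, mu)
      triples in (E, log length_bp); exact at grid points.  Queries outside
      the grid raise :class:`MobilityRangeError` unless clamped-edge
      extrapolation is enabled.
    """

    def __init__(
        self,
        mode: str,
        *,
        mu0: float | None = None,
        beta: float | None = None,
        gamma: float | None = None,
        kuhn_bp: float = DEFAULT_KUHN_BP,
        table: pd.DataFrame | None = None,
        extrapolate: bool = False,
    ) -> None:
        if mode not in ("parametric", "table"):
            raise ValueError(f"mode must be 'parametric' or 'table', got {mode!r}")
        self.mode = mode
        self.kuhn_bp = float(kuhn_bp)
        self.extrapolate = bool(extrapolate)
        if mode == "parametric":
            if mu0 is None or beta is None or gamma is None:
                raise ValueError("parametric mode requires mu0, beta and gamma")
            if mu0 <= 0 or beta < 0 or gamma < 0:
                raise ValueError("parametric mode requires mu0 > 0, beta >= 0, gamma >= 0")
            self.mu0, self.beta, self.gamma = float(mu0), float(beta), float(gamma)
            self._E_grid = self._L_grid = self._mu_grid = None
        else:
            if table is None:
                raise ValueError("table mode requires a calibration table")
            self._ingest_table(table)

    # ------------------------------------------------------------------ table
    def _ingest_table(self, table: pd.DataFrame) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"calibration table missing columns {missing}")
        tab = table[list(TABLE_COLUMNS)].astype(float)
        E = np.unique(tab["E_V_per_cm"].to_numpy())
        L = np.unique(tab["length_bp"].to_numpy())
        grid = (
            tab.pivot_table(
                index="length_bp", columns="E_V_per_cm", values="mobility_cm2_per_Vs"
            )
            .reindex(index=L, columns=E)
            .to_numpy()
        )
        if np.isnan(grid).any():
            raise ValueError("calibration table is not a complete (E, length) grid")
        if (grid <= 0).any():
            raise ValueError("calibration mobilities must be positive")
        self._E_grid, self._L_grid, self._mu_grid = E, L, grid
        self.table = tab.sort_values(["length_bp", "E_V_per_cm"]).reset_index(drop=True)

    def _check_range(self, value: float, grid: np.ndarray, axis: str) -> float:
        if grid[0] <= value <= grid[-1]:
            return value
        if self.extrapolate:
            return float(np.clip(value, grid[0], grid[-1]))
        raise MobilityRangeError(
            f"{axis}={value:g} outside table range [{grid[0]:g}, {grid[-1]:g}] "
            "(enable extrapolate=True for clamped-edge extrapolation)"
        )

    def _table_eval(self, E: float, length_bp: float) -> float:
        E = self._check_range(E, self._E_grid, "E_V_per_cm")
        length_bp = self._check_range(length_bp, self._L_grid, "length_bp")
        iE = np.searchsorted(self._E_grid, E, side="right") - 1
        iE = min(max(iE, 0), len(self._E_grid) - 2) if len(self._E_grid) > 1 else 0
        iL = np.searchsorted(self._L_grid, length_bp, side="right") - 1
        iL = min(max(iL, 0), len(self._L_grid) - 2) if len(self._L_grid) > 1 else 0
        # exact grid hits return the tabulated value untouched
        jE = np.searchsorted(self._E_grid, E)
        jL = np.searchsorted(self._L_grid, length_bp)
        hitE = jE < len(self._E_grid) and self._E_grid[jE] == E
        hitL = jL < len(self._L_grid) and self._L_grid[jL] == length_bp
        if hitE and hitL:
            return float(self._mu_grid[jL, jE])
        # bilinear in (E, log length)
        E0, E1 = self._E_grid[iE], self._E_grid[iE + 1]
        L0, L1 = self._L_grid[iL], self._L_grid[iL + 1]
        tE = 0.0 if E1 == E0 else (E - E0) / (E1 - E0)
        tL = 0.0 if L1 == L0 else (math.log(length_bp) - math.log(L0)) / (
            math.log(L1) - math.log(L0)
        )
        m = self._mu_grid
        return float(
            (1 - tE) * (1 - tL) * m[iL, iE]
            + tE * (1 - tL) * m[iL, iE + 1]
            + (1 - tE) * tL * m[iL + 1, iE]
            + tE * tL * m[iL + 1, iE + 1]
        )

    # ------------------------------------------------------------- evaluation
    def mobility(self, E: float, fragment: FragmentSpec) -> float:
        """Evaluate mu(E, L) in cm^2/(V s)."""
        if E <= 0:
            raise ValueError(f"field strength must be positive, got E={E}")
        if self.mode == "parametric":
            N = fragment.length_bp / self.kuhn_bp
            return self.mu0 * (1.0 / (3.0 * N) + self.beta * E**2 / (1.0 + self.gamma * E**2))
        return self._table_eval(float(E), float(fragment.length_bp))

    def mobility_derivative(self, E: float, fragment: FragmentSpec) -> float:
        """d(mu)/dE at (E, L).

        Closed form in parametric mode; central finite difference with step
        h = 1% of the local E grid spacing in table mode (one-sided at the
        grid edges).
        """
        if E <= 0:
            raise ValueError(f"field strength must be positive, got E={E}")
        if self.mode == "parametric":
            denom = 1.0 + self.gamma * E**2
            return self.mu0 * self.beta * 2.0 * E / denom**2
        Eg = self._E_grid
        E = self._check_range(float(E), Eg, "E_V_per_cm")
        i = min(max(np.searchsorted(Eg, E, side="right") - 1, 0), len(Eg) - 2)
        h = 0.01 * (Eg[i + 1] - Eg[i])
        lo, hi = E - h, E + h
        if lo < Eg[0]:
            lo = E
        if hi > Eg[-1]:
            hi = E
        if hi == lo:
            raise MobilityRangeError("degenerate derivative stencil")
        f = lambda x: self._table_eval(x, float(fragment.length_bp))
        return (f(hi) - f(lo)) / (hi - lo)

    def delta_mobility(self, E1: float, E2: float, fragment: FragmentSpec) -> float:
        """Mobility gain between the strong and weak field.

        Delta-mu = d(mu)/dE * (E1 - E2), with the derivative evaluated at the
        midpoint (E1 + E2)/2 (second-order accurate convention).
        """
        if not (E1 > E2 > 0):
            raise ValueError(f"require E1 > E2 > 0, got E1={E1}, E2={E2}")
        return self.mobility_derivative(0.5 * (E1 + E2), fragment) * (E1 - E2)

    # -------------------------------------------------------------------- io
    def to_yaml(self, path) -> None:
        if self.mode != "parametric":
            raise ValueError("YAML serialization applies to parametric models")
        blob = {
            "mode": "parametric",
            "mu0": self.mu0,
            "beta": self.beta,
            "gamma": self.gamma,
            "kuhn_bp": self.kuhn_bp,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(blob, fh)

    @classmethod
    def from_yaml(cls, path) -> "MobilityModel":
        with open(path) as fh:
            blob = yaml.safe_load(fh)
        mode = blob.pop("mode", "parametric")
        if mode != "parametric":
            raise ValueError(f"unsupported mode in YAML: {mode!r}")
        return cls("parametric", **blob)

    def to_csv(self, path) -> None:
        if self.mode != "table":
            raise ValueError("CSV serialization applies to table models")
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, *, extrapolate: bool = False) -> "MobilityModel":
        return cls("table", table=pd.read_csv(path), extrapolate=extrapolate)


# ----------------------------------------------------------------- kinetics
def reorientation_time(mu: float, E: float, fragment: FragmentSpec) -> KineticsResult:
    """Reorientation kinetics t_or = L/(mu E), f_or = 1/(2 t_or) = mu E/(2 L)."""
    if mu <= 0 or E <= 0:
        raise ValueError(f"require mu > 0 and E > 0, got mu={mu}, E={E}")
    L = fragment.contour_length_cm
    if L == 0.0:
        return KineticsResult(0.0, math.inf, E, fragment)
    t_or = L / (mu * E)
    return KineticsResult(t_or, 1.0 / (2.0 * t_or), E, fragment)


def reorientation_frequency(mu: float, E: float, fragment: FragmentSpec) -> float:
    """f_or = mu E / (2 L) in Hz."""
    return reorientation_time(mu, E, fragment).f_or_Hz


# ---------------------------------------------------------- synthetic table
#: E grid of the packaged synthetic calibration table (V/cm); spans the
#: 1-135 V/cm operating range and contains the protocol fields used in the
#: worked examples.
SYNTHETIC_E_GRID = (5.0, 10.0, 22.4, 24.6, 29.1, 40.0, 59.5, 89.8, 134.6)
SYNTHETIC_LENGTHS_BP = (500, 1000, 2000, 5000, 10000)

# Saturation field scale of the synthetic family, V/cm.
_SYNTH_E_SAT = 60.0
# Per-length (scale A, field-response b); A decreasing with length (coil
# friction), A*b increasing over 0.5-5 kbp (field response grows with
# length), b equal for 5 and 10 kbp so their mobility ratios between any
# two fields coincide exactly and biased reptation alone cannot separate
# them.  The 10 kbp scale is anchored so mu(59.5 V/cm, 10 kbp) = 2.75e-5
# cm^2/(V s), the value implied by a 2.4 Hz reorientation frequency.
_SYNTH_B = {500: 0.4, 1000: 0.8, 2000: 1.4, 5000: 2.2, 10000: 2.2}
_SYNTH_A = {500: 7.2e-5, 1000: 5.2e-5, 2000: 3.6e-5, 5000: 2.5214e-5}
_ANCHOR_E, _ANCHOR_L, _ANCHOR_MU = 59.5, 10000, 2.75e-5


def _synth_shape(E: float) -> float:
    return E**2 / (_SYNTH_E_SAT**2 + E**2)


def synthetic_calibration_table() -> pd.DataFrame:
    """Packaged synthetic (E, length, mu) calibration grid.

    Emulates the qualitative structure of mobility measurements for
    0.5-10 kbp dsDNA in 1.2% agarose: mu increases with E and decreases
    with length; the mobility gain Delta-mu between a strong and a weak
    field grows with length over 0.5-5 kbp; and the 5 and 10 kbp fragments
    share the same strong/weak mobility ratio.  Synthetic -- not fitted to
    any measured dataset.
    """
    a10 = _ANCHOR_MU / (1.0 + _SYNTH_B[_ANCHOR_L] * _synth_shape(_ANCHOR_E))
    A = {**_SYNTH_A, 10000: a10}
    rows = [
        (E, L, A[L] * (1.0 + _SYNTH_B[L] * _synth_shape(E)))
        for L in SYNTHETIC_LENGTHS_BP
        for E in SYNTHETIC_E_GRID
    ]
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def synthetic_mobility_model(*, extrapolate: bool = False) -> MobilityModel:
    """Table-mode :class:`MobilityModel` over the packaged synthetic grid."""
    return MobilityModel("table", table=synthetic_calibration_table(), extrapolate=extrapolate)
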
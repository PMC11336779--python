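"""Zone-coefficient step-length correction and its calibration.

The raw pendulum estimate over-shoots long steps and under-shoots short ones.
The correction multiplies each raw step length by a constant chosen by which
step-length band ("zone") the *raw* estimate falls in:

    adjusted = c(zone(raw)) · raw

The built-in coefficient tables (for zones 0.2–0.5 / 0.5–0.8 / 0.8–1.1 m) are
the published defaults for pooled, normal-walking-only and dual-task-only
calibration data. Calibration against a reference system fits one coefficient
per zone as the ratio of means, and an interval search scans candidate zone
widths (0.10…0.50 m in 0.05 m increments, grid anchored at 0.2 m), scoring
each width by the Passing–Bablok slope/intercept of adjusted-vs-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ParameterError, ValidationError
from .stats import passing_bablok

log = logging.getLogger(__name__)

#: Published zone edges (m) shared by all built-in coefficient tables.
DEFAULT_ZONE_EDGES = (0.2, 0.5, 0.8, 1.1)

#: Published multiplicative coefficients per condition.
_TABLE_COEFFS = {
    "all": (1.37, 1.02, 0.74),
    "normal": (1.40, 1.04, 0.74),
    "dual_task": (1.36, 1.01, 0.73),
}

#: Candidate zone widths (m) scanned by the interval search.
DEFAULT_WIDTHS = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))

#: Grid anchor (m): zone edges sit at anchor + k·width for every width.
DEFAULT_ANCHOR = 0.2


@dataclass
class CoefficientTable:
    """Ordered step-length zones with one positive multiplier per zone.

    ``zone_edges`` are ascending breakpoints; zone k is the half-open interval
    [edges[k], edges[k+1]), except the last zone which is closed. Inputs
    outside the edges use the nearest zone's coefficient and are flagged.
    ``inherited`` marks zones whose coefficient was copied from the nearest
    populated neighbour during fitting (fewer than 2 calibration pairs).
    """

    zone_edges: np.ndarray
    coefficients: np.ndarray
    condition: str = "all"
    inherited: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zone_edges = np.asarray(self.zone_edges, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.zone_edges) - 1:
            raise ValidationError("need exactly one coefficient per zone")
        if np.any(np.diff(self.zone_edges) <= 0):
            raise ValidationError("zone edges must be strictly increasing")
        if np.any(self.coefficients <= 0):
            raise ValidationError("coefficients must be positive")
        if self.inherited is None:
            self.inherited = np.zeros(len(self.coefficients), dtype=bool)

    @property
    def n_zones(self) -> int:
        return len(self.coefficients)

    def zone_of(self, x) -> np.ndarray:
        """Zone index for each value, clipping out-of-range inputs to the nearest zone."""
        x = np.asarray(x, dtype=float)
        z = np.searchsorted(self.zone_edges, x, side="right") - 1
        # values equal to the last edge belong to the (closed) last zone
        z = np.where(x == self.zone_edges[-1], self.n_zones - 1, z)
        return np.clip(z, 0, self.n_zones - 1)

    def zone_label(self, k: int) -> str:
        return f"{self.zone_edges[k]:g}-{self.zone_edges[k + 1]:g}"

    def to_yaml(self, path) -> None:
        doc = {
            "zone_edges": [float(e) for e in self.zone_edges],
            "coefficients": [float(c) for c in self.coefficients],
            "condition": self.condition,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoefficientTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls(
                zone_edges=doc["zone_edges"],
                coefficients=doc["coefficients"],
                condition=doc.get("condition", "all"),
            )
        except (KeyError, TypeError) as e:
            raise ValidationError(f"malformed coefficient file {path}: {e}") from e


@dataclass
class PairedSteps:
    """Paired app-estimated and reference step lengths (m), order preserved."""

    est: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if len(self.est) != len(self.ref):
            raise ValidationError("est and ref must have equal length")
        if len(self.est) < 2:
            raise ValidationError("need at least 2 pairs")
        if np.any(self.est <= 0) or np.any(self.ref <= 0):
            raise ValidationError("step lengths must be positive")

    def __len__(self) -> int:
        return len(self.est)


@dataclass
class IntervalSearchResult:
    """Per-width Passing–Bablok fit of adjusted-vs-reference and the selected width."""

    widths: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    selected_width: float
    tables: dict = field(default_factory=dict)

    def report(self) -> str:
        lines = ["width_m  slope  intercept_m"]
        for w, s, a in zip(self.widths, self.slopes, self.intercepts):
            mark = " *" if w == self.selected_width else ""
            lines.append(f"{w:7.2f}  {s:5.2f}  {a:11.2f}{mark}")
        lines.append(f"selected width: {self.selected_width:.2f} m")
        return "\n".join(lines)


def default_coefficients(condition: str = "all") -> CoefficientTable:
    """Built-in published coefficient table for a walking condition."""
    if condition not in _TABLE_COEFFS:
        raise ParameterError(
            f"unknown condition {condition!r}; expected one of {sorted(_TABLE_COEFFS)}"
        )
    return CoefficientTable(
        zone_edges=DEFAULT_ZONE_EDGES,
        coefficients=_TABLE_COEFFS[condition],
        condition=condition,
    )


def apply_adjustment(step_length, coeffs: CoefficientTable):
    """Multiply step length(s) by the coefficient of the zone of the *raw* value.

    Returns ``(adjusted, zone_index, out_of_range)``; all three are scalars for
    scalar input, arrays otherwise. Out-of-range inputs use the nearest zone's
    coefficient and are flagged.
    """
    x = np.asarray(step_length, dtype=float)
    scalar = x.ndim == 0
    if np.any(x <= 0):
        raise ValidationError("step length must be positive")
    z = coeffs.zone_of(x)
    out_of_range = (x < coeffs.zone_edges[0]) | (x > coeffs.zone_edges[-1])
    adjusted = coeffs.coefficients[z] * x
    if scalar:
        return float(adjusted), int(z), bool(out_of_range)
    return adjusted, z, out_of_range


def adjust_stride_table(table, coeffs: CoefficientTable):
    """Fill the adjusted columns of a stride table in place (and return it).

    Adjusted speed is recomputed from the adjusted step lengths through the
    same stride-length/stride-time formula, never by scaling raw speed.
    """
    if len(table) == 0:
        return table
    for step in (1, 2):
        adj, z, oor = apply_adjustment(table[f"step_length_{step}_m"].to_numpy(), coeffs)
        table[f"step_length_adj_{step}_m"] = adj
        labels = [coeffs.zone_label(k) + ("!" if o else "") for k, o in zip(z, oor)]
        table[f"zone_{step}"] = labels
    sl_adj = table["step_length_adj_1_m"] + table["step_length_adj_2_m"]
    table["speed_adj_mps"] = sl_adj / table["stride_time_s"]
    return table


def _zone_grid(est: np.ndarray, width: float, anchor: float) -> np.ndarray:
    """Edges anchor + k·width covering the observed est range."""
    k_lo = int(np.floor((est.min() - anchor) / width + 1e-12))
    k_hi = int(np.ceil((est.max() - anchor) / width - 1e-12))
    k_hi = max(k_hi, k_lo + 1)
    return anchor + width * np.arange(k_lo, k_hi + 1)


def fit_zone_coefficients(
    paired: PairedSteps,
    width: float,
    anchor: float = DEFAULT_ANCHOR,
    condition: str = "all",
) -> CoefficientTable:
    """Fit one multiplicative coefficient per zone as mean(ref)/mean(est).

    The ratio of means equals 1 under no bias and is the through-origin
    least-squares slope under multiplicative error. Zones with fewer than two
    pairs inherit the nearest populated zone's coefficient and are flagged in
    ``inherited``.
    """
    if width <= 0:
        raise ParameterError(f"zone width must be positive, got {width}")
    est, ref = paired.est, paired.ref
    edges = _zone_grid(est, width, anchor)
    n_zones = len(edges) - 1
    z = np.clip(np.searchsorted(edges, est, side="right") - 1, 0, n_zones - 1)
    coefs = np.full(n_zones, np.nan)
    for k in range(n_zones):
        sel = z == k
        if sel.sum() >= 2:
            coefs[k] = ref[sel].mean() / est[sel].mean()
    populated = np.where(np.isfinite(coefs))[0]
    if len(populated) == 0:
        raise ValidationError("no zone holds at least two calibration pairs")
    inherited = ~np.isfinite(coefs)
    if inherited.any():
        log.warning(
            "%d of %d zones have <2 pairs; inheriting nearest populated coefficient",
            int(inherited.sum()),
            n_zones,
        )
    for k in np.where(inherited)[0]:
        coefs[k] = coefs[populated[np.argmin(np.abs(populated - k))]]
    return CoefficientTable(
        zone_edges=edges, coefficients=coefs, condition=condition, inherited=inherited
    )


def select_interval(
    paired: PairedSteps,
    widths=DEFAULT_WIDTHS,
    anchor: float = DEFAULT_ANCHOR,
) -> IntervalSearchResult:
    """Scan candidate zone widths and pick the one with the best agreement.

    For each width: fit coefficients on ``paired``, adjust the estimates, and
    regress adjusted on reference with Passing–Bablok. The selected width
    minimises |slope − 1|, with ties broken by smaller |intercept| and then by
    smaller width. The result is a deterministic function of the inputs.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ParameterError("widths must be non-empty")
    slopes = np.empty(len(widths))
    intercepts = np.empty(len(widths))
    tables = {}
    for idx, w in enumerate(widths):
        tab = fit_zone_coefficients(paired, float(w), anchor=anchor)
        adjusted, _, _ = apply_adjustment(paired.est, tab)
        pb = passing_bablok(paired.ref, adjusted)
        slopes[idx], intercepts[idx] = pb.slope, pb.intercept
        tables[float(w)] = tab
    order = sorted(
        range(len(widths)),
        key=lambda i: (abs(slopes[i] - 1.0), abs(intercepts[i]), widths[i]),
    )
    best = order[0]
    return IntervalSearchResult(
        widths=widths,
        slopes=slopes,
        intercepts=intercepts,
        selected_width=float(widths[best]),
        tables=tables,
    )
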
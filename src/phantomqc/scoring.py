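"""ACR phantom point rules and score sheets.

A reviewer (or model) awards each of the 16 targets 0, 0.5 or 1 point.
Fibres and masses score directly from visibility; microcalcification
groups score from the number of visible specks (fewer than three specks:
0 points; exactly three: half a point; more than three: one point).
Per-family totals (fibres out of 6, speck groups out of 5, masses out of
5) are compared against site acceptance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classes import NONV, position_to_class
from .errors import InvalidArgumentError

_LEVELS = {"not_visible": 0.0, "barely_visible": 0.5, "visible": 1.0}
_VALID_POINTS = (0.0, 0.5, 1.0)

#: Conventional site acceptance thresholds (fibres, mc groups, masses).
#: Not taken from any single publication; configure to local policy.
DEFAULT_PASS_THRESHOLDS = (4.0, 3.0, 3.0)


def score_fibre_or_mass(visibility: str) -> float:
    """Map a visibility judgement to ACR points (0 / 0.5 / 1)."""
    try:
        return _LEVELS[visibility]
    except KeyError:
        raise InvalidArgumentError(
            f"visibility must be one of {sorted(_LEVELS)}, got {visibility!r}")


def score_mc_group(n_visible_specks: int) -> float:
    """ACR counting rule for a microcalcification group.

    Fewer than three visible specks score 0, exactly three score 0.5,
    more than three score 1.
    """
    n = int(n_visible_specks)
    if n < 0:
        raise InvalidArgumentError("speck count must be non-negative")
    if n < 3:
        return 0.0
    if n == 3:
        return 0.5
    return 1.0


@dataclass
class ScoreSheet:
    """Per-target points for one phantom image, grouped by target family."""

    fibre_points: list[float]
    mc_points: list[float]
    mass_points: list[float]
    source: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if len(self.fibre_points) != 6 or len(self.mc_points) != 5 \
                or len(self.mass_points) != 5:
            raise InvalidArgumentError("expected 6 fibre, 5 mc, 5 mass points")
        for p in (*self.fibre_points, *self.mc_points, *self.mass_points):
            if p not in _VALID_POINTS:
                raise InvalidArgumentError(f"points must be in {_VALID_POINTS}")

    @property
    def fibre_total(self) -> float:
        return float(sum(self.fibre_points))

    @property
    def mc_total(self) -> float:
        return float(sum(self.mc_points))

    @property
    def mass_total(self) -> float:
        return float(sum(self.mass_points))

    @property
    def totals(self) -> tuple[float, float, float]:
        return (self.fibre_total, self.mc_total, self.mass_total)

    @classmethod
    def from_points(cls, points: dict[int, float], **kw) -> "ScoreSheet":
        """Build a sheet from a position (1..16) -> point mapping."""
        if sorted(points) != list(range(1, 17)):
            raise InvalidArgumentError("need exactly positions 1..16")
        return cls(
            fibre_points=[points[p] for p in range(1, 7)],
            mc_points=[points[p] for p in range(7, 12)],
            mass_points=[points[p] for p in range(12, 17)],
            **kw,
        )

    def as_row(self) -> dict:
        """Flat dict (CSV row) with 16 points, totals, and provenance."""
        row = {"image_id": self.image_id, "source": self.source}
        for i, p in enumerate(self.fibre_points, 1):
            row[f"f{i}"] = p
        for i, p in enumerate(self.mc_points, 1):
            row[f"c{i}"] = p
        for i, p in enumerate(self.mass_points, 1):
            row[f"m{i}"] = p
        row["fibre_total"], row["mc_total"], row["mass_total"] = self.totals
        return row


def predictions_to_sheet(predictions: dict[int, object], mode: str = "strict",
                         source: str = "cnn", image_id: str = "") -> ScoreSheet:
    """Aggregate 16 per-position CNN predictions into an ACR score sheet.

    ``predictions`` maps each position 1..16 to an object with a
    ``top_class`` attribute (or a bare class-name string).  In ``strict``
    mode a target counts as visible only when the predicted class matches
    the position's own class; in ``lenient`` mode any non-``nonv``
    prediction counts.  Model sheets carry no half points.
    """
    if sorted(predictions) != list(range(1, 17)):
        raise InvalidArgumentError("need one prediction per position 1..16")
    if mode not in ("strict", "lenient"):
        raise InvalidArgumentError("mode must be 'strict' or 'lenient'")
    points = {}
    for pos, pred in predictions.items():
        top = getattr(pred, "top_class", pred)
        if mode == "strict":
            visible = top == position_to_class(pos)
        else:
            visible = top != NONV
        points[pos] = 1.0 if visible else 0.0
    return ScoreSheet.from_points(points, source=source, image_id=image_id)


def sheet_passes(sheet: ScoreSheet,
                 thresholds: tuple[float, float, float] = DEFAULT_PASS_THRESHOLDS,
                 ) -> bool:
    """True when every per-family total meets its acceptance threshold."""
    if thresholds is None or len(thresholds) != 3:
        raise InvalidArgumentError("thresholds must be three values")
    return all(t >= thr for t, thr in zip(sheet.totals, thresholds))
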
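"""The 17-way classification scheme shared across modules.

Positions 1..16 index the phantom targets in reading order: six fibres,
five microcalcification groups, five masses.  The 17th category ("nonv")
pools every non-visible target regardless of position.
"""

CLASS_NAMES = (
    "f1", "f2", "f3", "f4", "f5", "f6",
    "c1", "c2", "c3", "c4", "c5",
    "m1", "m2", "m3", "m4", "m5",
    "nonv",
)

NONV = "nonv"

#: (kind, within-kind index) for positions 1..16
POSITION_KINDS = tuple(
    [("fibre", i) for i in range(1, 7)]
    + [("mc_group", i) for i in range(1, 6)]
    + [("mass", i) for i in range(1, 6)]
)


def position_to_class(position: int) -> str:
    """Class name of the visible target at a sub-image position (1..16)."""
    if not 1 <= position <= 16:
        raise ValueError(f"position must be 1..16, got {position}")
    return CLASS_NAMES[position - 1]


def class_index(name: str) -> int:
    """Integer label (0..16) of a class name."""
    return CLASS_NAMES.index(name)
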
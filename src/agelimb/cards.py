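"""LS-DYNA keyword material-card export.

Writes the per-age material tables as solver-ready material cards in the
10-column fixed-width keyword convention: cortical bone as
*MAT_PIECEWISE_LINEAR_PLASTICITY (with Cowper–Symonds C and P), cancellous
bone as *MAT_PLASTIC_KINEMATIC, and the knee ligament as *MAT_SOFT_TISSUE.
Only fields the material tables populate are emitted; the rest are
zero-filled.  Unit system on the cards: mm, ms, g, N, MPa (densities are
converted from kg/m^3 to g/mm^3).

The writer is deterministic and round-trips through :func:`parse_cards`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError
from .materials import (
    AgeMaterialSet,
    COWPER_SYMONDS_C,
    COWPER_SYMONDS_P,
)

FIELD_WIDTH = 10

KEYWORDS = (
    "*MAT_PIECEWISE_LINEAR_PLASTICITY",
    "*MAT_PLASTIC_KINEMATIC",
    "*MAT_SOFT_TISSUE",
)


def _fmt(v: float) -> str:
    """Render a value into a fixed 10-character keyword field."""
    s = f"{v:{FIELD_WIDTH}.6g}"
    if len(s) > FIELD_WIDTH:
        s = f"{v:{FIELD_WIDTH}.3e}"
    return s[:FIELD_WIDTH].rjust(FIELD_WIDTH)


def _quantize(v: float) -> float:
    """The value as it survives the fixed-width format (lossless round trip)."""
    return float(_fmt(v))


@dataclass(frozen=True)
class MaterialCard:
    """One keyword material card: field names and (quantized) values."""

    keyword: str
    title: str
    names: tuple[tuple[str, ...], ...]   # per data row
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if self.keyword not in KEYWORDS:
            raise DomainError(f"unsupported keyword {self.keyword!r}")
        for n, v in zip(self.names, self.values):
            if len(n) != len(v):
                raise DomainError("field names and values must align")

    def field(self, name: str) -> float:
        for row_n, row_v in zip(self.names, self.values):
            if name in row_n:
                return row_v[row_n.index(name)]
        raise KeyError(name)


def _card(keyword: str, title: str, rows: list[list[tuple[str, float]]]) -> MaterialCard:
    return MaterialCard(
        keyword=keyword,
        title=title,
        names=tuple(tuple(n for n, _ in row) for row in rows),
        values=tuple(tuple(_quantize(v) for _, v in row) for row in rows),
    )


def cards_from_materials(mats: AgeMaterialSet) -> list[MaterialCard]:
    """Build the card stack (6 bone cards + 1 ligament card) for one age."""
    cards = []
    mid = 1
    for bone in ("femur", "tibia", "fibula"):
        c = mats.cortical[bone]
        cards.append(_card(
            "*MAT_PIECEWISE_LINEAR_PLASTICITY",
            f"{bone} cortical, age {mats.age:g}",
            [
                [("mid", mid), ("ro", c.density * 1e-6),
                 ("e", c.elastic_modulus * 1000.0), ("pr", c.poisson),
                 ("sigy", c.yield_stress), ("etan", c.tangent_modulus),
                 ("fail", c.failure_strain), ("tdel", 0.0)],
                [("c", COWPER_SYMONDS_C), ("p", COWPER_SYMONDS_P),
                 ("lcss", 0.0), ("lcsr", 0.0), ("vp", 0.0)],
            ],
        ))
        mid += 1
        n = mats.cancellous[bone]
        cards.append(_card(
            "*MAT_PLASTIC_KINEMATIC",
            f"{bone} cancellous, age {mats.age:g}",
            [
                [("mid", mid), ("ro", n.density * 1e-6),
                 ("e", n.elastic_modulus), ("pr", n.poisson),
                 ("sigy", n.yield_stress), ("etan", 0.0), ("beta", 0.0)],
                [("src", 0.0), ("srp", 0.0), ("fs", n.failure_strain), ("vp", 0.0)],
            ],
        ))
        mid += 1
    lig = mats.ligament
    cards.append(_card(
        "*MAT_SOFT_TISSUE",
        f"knee ligament, age {mats.age:g}",
        [
            [("mid", mid), ("ro", lig.density * 1e-6), ("c1", lig.C1),
             ("c2", 0.0), ("c3", lig.C3), ("c4", lig.C4), ("c5", lig.C5)],
            [("xk", lig.bulk_modulus * 1000.0), ("xlam", lig.lambda_star),
             ("fs", lig.failure_strain)],
        ],
    ))
    return cards


def render_cards(cards: list[MaterialCard]) -> str:
    lines = [
        "$ agelimb material cards",
        "$ units: mm / ms / g / N / MPa (ro in g/mm^3, e and sigy in MPa)",
    ]
    for card in cards:
        lines.append(f"$ {card.title}")
        lines.append(card.keyword + "_TITLE")
        lines.append(card.title)
        for row_n, row_v in zip(card.names, card.values):
            lines.append("$#" + "".join(n.rjust(FIELD_WIDTH) for n in row_n)[2:])
            lines.append("".join(_fmt(v) for v in row_v))
    lines.append("*END")
    return "\n".join(lines) + "\n"


def write_cards(mats: AgeMaterialSet, path) -> list[MaterialCard]:
    """Write the keyword file for one age; returns the cards written."""
    cards = cards_from_materials(mats)
    with open(path, "w") as fh:
        fh.write(render_cards(cards))
    return cards


def parse_cards(path) -> list[MaterialCard]:
    """Parse a keyword file written by :func:`write_cards`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    cards: list[MaterialCard] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("*MAT"):
            keyword = line.removesuffix("_TITLE")
            title = lines[i + 1].strip()
            i += 2
            names, values = [], []
            while i < len(lines) and not lines[i].startswith(("*", "$ ")):
                header = lines[i]
                if not header.startswith("$#"):
                    raise DomainError(f"malformed card near line {i + 1}")
                data = lines[i + 1]
                row_names = ("$#" + header[2:]).replace("$#", "  ")
                n_fields = (len(data) + FIELD_WIDTH - 1) // FIELD_WIDTH
                names.append(tuple(
                    row_names[j * FIELD_WIDTH:(j + 1) * FIELD_WIDTH].strip()
                    for j in range(n_fields)
                ))
                values.append(tuple(
                    float(data[j * FIELD_WIDTH:(j + 1) * FIELD_WIDTH])
                    for j in range(n_fields)
                ))
                i += 2
            cards.append(MaterialCard(keyword=keyword, title=title,
                                      names=tuple(names), values=tuple(values)))
        else:
            i += 1
    return cards
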
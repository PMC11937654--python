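"""C1·V1 = C2·V2 arithmetic for the assay's reaction recipes.

Every wet-lab mix in the workflow — oligo annealing, the Cas12a/crRNA/
reporter detection mastermix, PCR and isothermal (RPA) amplification — is
a list of components given as stock and final concentration (or a fixed
pipetting volume), filled to the reaction volume with water.  Volumes are
rounded to 2 decimals half-up, the convention that reproduces sub-0.1 µL
cells such as 0.08 µL Cas12a and 0.07 µL RPA primers; the water fill
absorbs the rounding residue so each recipe conserves volume exactly.

Units: molar (M/mM/µM/nM/pM), enzymatic activity (U/mL, U/µL), fold
("x", e.g. a 10x buffer diluted to 1x), and mass-per-volume (ng/µL).
Volumes are µL throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "Quantity",
    "Component",
    "ReactionRecipe",
    "UnitError",
    "mix_volume",
    "build_recipe",
    "anneal_concentration",
    "annealing_recipe",
    "crisprdx_mastermix_recipe",
    "pcr_recipe",
    "rpa_recipe",
    "BUILTIN_RECIPES",
]


class UnitError(ValueError):
    """Unknown unit or dimensionally incompatible concentrations."""


_UNIT_TABLE: dict[str, tuple[str, float]] = {
    "M": ("molar", 1.0),
    "mM": ("molar", 1e-3),
    "uM": ("molar", 1e-6),
    "nM": ("molar", 1e-9),
    "pM": ("molar", 1e-12),
    "U/mL": ("activity", 1.0),
    "U/uL": ("activity", 1e3),
    "x": ("fold", 1.0),
    "ng/uL": ("mass_conc", 1.0),
}


def _normalize_unit(unit: str) -> str:
    u = unit.strip().replace("µ", "u").replace("μ", "u")
    u = u.replace("ul", "uL").replace("ml", "mL")
    if u.lower() == "x":
        return "x"
    for known in _UNIT_TABLE:
        if u == known or u.lower() == known.lower():
            return known
    raise UnitError(f"unknown concentration unit {unit!r}")


@dataclass(frozen=True)
class Quantity:
    """A concentration: numeric value plus unit (e.g. ``Quantity(10, "uM")``)."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalize_unit(self.unit))
        if self.value <= 0:
            raise ValueError(f"concentration must be positive, got {self.value}")

    @property
    def dimension(self) -> str:
        return _UNIT_TABLE[self.unit][0]

    @property
    def base_value(self) -> float:
        return self.value * _UNIT_TABLE[self.unit][1]

    @classmethod
    def parse(cls, text: str) -> "Quantity":
        m = re.fullmatch(r"\s*([\d.eE+-]+)\s*([^\s]+)\s*", text)
        if not m:
            raise UnitError(f"cannot parse concentration {text!r}")
        return cls(float(m.group(1)), m.group(2))

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit}"


@dataclass(frozen=True)
class Component:
    """One recipe ingredient.

    Either ``stock``/``final`` concentrations (volume computed by dilution
    arithmetic) or a ``fixed_volume`` in µL (e.g. "2 µL template", where
    the concentration is sample-dependent).  ``note`` carries handling
    annotations such as "add last".
    """

    name: str
    stock: Quantity | None = None
    final: Quantity | None = None
    fixed_volume: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.fixed_volume is None:
            if self.stock is None or self.final is None:
                raise ValueError(
                    f"{self.name}: needs stock+final concentrations or a fixed volume"
                )
            if self.stock.dimension != self.final.dimension:
                raise UnitError(
                    f"{self.name}: incompatible units "
                    f"{self.stock.unit} vs {self.final.unit}"
                )
            if self.final.base_value > self.stock.base_value:
                raise ValueError(
                    f"{self.name}: final {self.final} exceeds stock {self.stock}"
                )
        elif self.fixed_volume <= 0:
            raise ValueError(f"{self.name}: fixed volume must be positive")


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mix_volume(stock: Quantity, final: Quantity, total_ul: float) -> float:
    """Volume of stock (µL) to reach ``final`` in ``total_ul``: V = total·final/stock,
    rounded to 2 decimals half-up."""
    if stock.dimension != final.dimension:
        raise UnitError(f"incompatible units {stock.unit} vs {final.unit}")
    if final.base_value > stock.base_value:
        raise ValueError(f"final {final} exceeds stock {stock}")
    return _round2(total_ul * final.base_value / stock.base_value)


@dataclass(frozen=True)
class ReactionRecipe:
    """A reaction: components with computed per-reaction volumes plus water fill."""

    name: str
    total_volume: float
    components: tuple[Component, ...]
    volumes: tuple[float, ...]
    water: float

    def volume_of(self, component_name: str) -> float:
        for comp, vol in zip(self.components, self.volumes):
            if comp.name == component_name:
                return vol
        raise KeyError(f"no component named {component_name!r} in {self.name}")

    def scaled(self, replicates: int = 1, surplus: float = 0.0) -> "ReactionRecipe":
        """Pure scaling for mastermix preparation, e.g. replicates × 1.1
        for the customary ~10% surplus."""
        if replicates < 1 or surplus < 0:
            raise ValueError("replicates must be >= 1 and surplus >= 0")
        factor = replicates * (1.0 + surplus)
        return replace(
            self,
            name=f"{self.name} (x{factor:g})",
            total_volume=_round2(self.total_volume * factor),
            volumes=tuple(_round2(v * factor) for v in self.volumes),
            water=_round2(self.water * factor),
        )

    def to_rows(self) -> list[dict[str, str | float]]:
        rows: list[dict[str, str | float]] = []
        for comp, vol in zip(self.components, self.volumes):
            rows.append(
                {
                    "reagent": comp.name,
                    "stock": str(comp.stock) if comp.stock else "-",
                    "final": str(comp.final) if comp.final else "-",
                    "volume_ul": vol,
                    "note": comp.note,
                }
            )
        rows.append({"reagent": "Water", "stock": "-", "final": "-",
                     "volume_ul": self.water, "note": "fill"})
        return rows


def build_recipe(
    components: list[Component], total_ul: float, name: str = "reaction"
) -> ReactionRecipe:
    """Compute per-component volumes and the water fill for one reaction.

    Volume conservation is exact: Σ volumes + water = total, with water
    absorbing the rounding residue.  A component sum beyond the total is
    an error reporting the overflow.
    """
    volumes = []
    for comp in components:
        if comp.fixed_volume is not None:
            volumes.append(_round2(comp.fixed_volume))
        else:
            volumes.append(mix_volume(comp.stock, comp.final, total_ul))
    used = float(sum(Decimal(repr(v)) for v in volumes))
    water = float(Decimal(repr(total_ul)) - Decimal(repr(used)))
    if water < 0:
        raise ValueError(
            f"{name}: component volumes exceed total by {-water:.2f} uL"
        )
    return ReactionRecipe(
        name=name,
        total_volume=total_ul,
        components=tuple(components),
        volumes=tuple(volumes),
        water=water,
    )


def anneal_concentration(
    oligo_volumes: list[float], oligo_stocks: list[Quantity], total_ul: float
) -> Quantity:
    """Duplex concentration after annealing two complementary oligos.

    The oligos must be equimolar (molar amounts within 1%); the duplex
    concentration is (stock × volume) / total of either oligo.
    """
    if len(oligo_volumes) != 2 or len(oligo_stocks) != 2:
        raise ValueError("annealing takes exactly two complementary oligos")
    if any(v <= 0 for v in oligo_volumes):
        raise ValueError("oligo volumes must be positive")
    if any(q.dimension != "molar" for q in oligo_stocks):
        raise UnitError("oligo stocks must be molar concentrations")
    amounts = [q.base_value * v for q, v in zip(oligo_stocks, oligo_volumes)]
    if abs(amounts[0] - amounts[1]) > 0.01 * max(amounts):
        raise ValueError(
            "oligos are not equimolar: "
            f"{amounts[0]:.4g} vs {amounts[1]:.4g} (molar amount x uL)"
        )
    duplex_molar = amounts[0] / total_ul
    return Quantity(duplex_molar / 1e-6, "uM")


# --- the protocol's standard mixes -------------------------------------------

def annealing_recipe(total_ul: float = 50.0) -> ReactionRecipe:
    """50 µL annealing mix forming a 10 µM dsDNA duplex from 100 µM oligos."""
    return build_recipe(
        [
            Component("ssDNA oligo 1", stock=Quantity(100, "uM"), fixed_volume=5.0),
            Component("ssDNA oligo 2", stock=Quantity(100, "uM"), fixed_volume=5.0),
            Component("SuRE/Cut buffer M", Quantity(10, "x"), Quantity(1, "x")),
        ],
        total_ul,
        name="dsDNA target annealing",
    )


def crisprdx_mastermix_recipe(total_ul: float = 20.0) -> ReactionRecipe:
    """20 µL Cas12a detection mastermix (40 nM Cas12a, 50 nM crRNA,
    100 nM FAM reporter) plus 2 µL target."""
    return build_recipe(
        [
            Component("CutSmart Buffer", Quantity(10, "x"), Quantity(1, "x")),
            Component("FAM reporter", Quantity(10, "uM"), Quantity(100, "nM")),
            Component("crRNA", Quantity(10, "uM"), Quantity(50, "nM")),
            Component("EnGen LbCas12a", Quantity(10, "uM"), Quantity(40, "nM")),
            Component("target DNA", fixed_volume=2.0, note="add last, outside mastermix"),
        ],
        total_ul,
        name="CRISPRdx mastermix",
    )


def pcr_recipe(total_ul: float = 15.0) -> ReactionRecipe:
    """15 µL hot-start PCR for target pre-amplification."""
    return build_recipe(
        [
            Component("DNA template", fixed_volume=2.0, note="0.5-10 ng"),
            Component("Q5 DNA Polymerase", Quantity(2000, "U/mL"), Quantity(20, "U/mL")),
            Component("forward primer", Quantity(10, "uM"), Quantity(500, "nM")),
            Component("reverse primer", Quantity(10, "uM"), Quantity(500, "nM")),
            Component("dNTP", Quantity(10, "mM"), Quantity(200, "uM")),
            Component("Buffer", Quantity(5, "x"), Quantity(1, "x")),
        ],
        total_ul,
        name="PCR",
    )


def rpa_recipe(total_ul: float = 15.0) -> ReactionRecipe:
    """15 µL isothermal (RPA) amplification; MgOAc starts the reaction and
    is added last."""
    return build_recipe(
        [
            Component("DNA template", fixed_volume=2.0, note="0.5-10 ng"),
            Component("Reaction buffer", Quantity(2, "x"), Quantity(1, "x")),
            Component("Forward primer", Quantity(100, "uM"), Quantity(467, "nM")),
            Component("Reverse primer", Quantity(100, "uM"), Quantity(467, "nM")),
            Component("dNTP", Quantity(10, "mM"), Quantity(900, "uM")),
            Component("E-mix", Quantity(10, "x"), Quantity(1, "x")),
            Component("Core mix", Quantity(20, "x"), Quantity(1, "x")),
            Component("MgOAc", Quantity(280, "mM"), Quantity(14, "mM"),
                      note="add last: starts the reaction"),
        ],
        total_ul,
        name="RPA",
    )


BUILTIN_RECIPES = {
    "annealing": annealing_recipe,
    "mastermix": crisprdx_mastermix_recipe,
    "crisprdx-mastermix": crisprdx_mastermix_recipe,
    "pcr": pcr_recipe,
    "rpa": rpa_recipe,
}
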
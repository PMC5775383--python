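"""Lipoplex formulation arithmetic.

Cationic liposomes (EPC/DOTAP/DOPE, 50/25/25 mol%) are assembled by
hydrodynamic focusing: an ethanolic lipid stream is squeezed between two
water streams, which dilutes the lipid by the flow-rate ratio.  The
liposomes are then complexed with plasmid DNA at a molar charge ratio

    R+/- = positive charges from cationic lipid / negative charges from pDNA

the lipid-world analogue of the N/P ratio.  Only DOTAP (+1 per molecule)
contributes positive charge; EPC and DOPE are net-neutral zwitterions.
Negative charges are counted as one per nucleotide at a mean molecular
mass of 330 g/mol per phosphate, the standard convention.

Units: concentrations in mM, volumes in uL (1 mM x 1 uL = 1 nmol),
droplet volumes in nL, pDNA mass in ug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import InvalidInputError

#: nominal charge ratios used across the experiments
NOMINAL_RATIOS = (1.5, 3.0, 5.0)

#: relative window within which a computed ratio snaps to a nominal one
NOMINAL_SNAP_WINDOW = 0.20

#: mean molecular mass of one nucleotide (one negative charge), g/mol
NUCLEOTIDE_MW = 330.0


@dataclass(frozen=True)
class LipidMix:
    """A lipid formulation: (name, molar fraction, elementary charge) triples
    plus the total lipid concentration in mM."""

    components: tuple[tuple[str, float, int], ...]
    total_lipid_concentration: float  # mM

    def __post_init__(self) -> None:
        fractions = sum(f for _, f, _ in self.components)
        if abs(fractions - 1.0) > 1e-9:
            raise InvalidInputError(
                f"molar fractions must sum to 1, got {fractions!r}"
            )
        if self.total_lipid_concentration < 0:
            raise InvalidInputError("total lipid concentration must be >= 0")

    @property
    def cationic_concentration(self) -> float:
        """Concentration of positive charge (mM), charge-weighted over the
        cationic components."""
        return self.total_lipid_concentration * sum(
            f * c for _, f, c in self.components if c > 0
        )


@dataclass(frozen=True)
class FocusingFlows:
    """Flow rates of the hydrodynamic-focusing junction (uL/min)."""

    center_flow: float
    side_flows: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.center_flow < 0 or any(q < 0 for q in self.side_flows):
            raise InvalidInputError("flow rates must be >= 0")
        if self.total <= 0:
            raise InvalidInputError("at least one flow must be positive")

    @property
    def total(self) -> float:
        return self.center_flow + sum(self.side_flows)

    @property
    def dilution_factor(self) -> float:
        return self.center_flow / self.total


@dataclass(frozen=True)
class LipoplexRecipe:
    """Inputs of a lipoplex preparation: pDNA mass complexed with a volume of
    the (post-dilution) liposome suspension, topped up to ``final_volume``."""

    pdna_mass: float  # ug
    liposome_volume: float  # uL
    final_volume: float  # uL
    liposome_cationic_concentration: float  # mM, post-dilution
    nucleotide_mw: float = NUCLEOTIDE_MW  # g/mol per negative charge

    def __post_init__(self) -> None:
        if self.pdna_mass < 0:
            raise InvalidInputError("pdna_mass must be >= 0")
        if self.liposome_volume < 0:
            raise InvalidInputError("liposome_volume must be >= 0")
        if self.final_volume <= 0:
            raise InvalidInputError("final_volume must be > 0")


@dataclass(frozen=True)
class RatioResult:
    """A computed charge ratio and, when close enough, its nominal label."""

    r_plus_minus: float
    nominal: float | None


def default_lipid_mix() -> LipidMix:
    """EPC/DOTAP/DOPE 50/25/25 mol% at 25 mM total lipid, as synthesized."""
    return LipidMix(
        components=(("EPC", 0.50, 0), ("DOTAP", 0.25, +1), ("DOPE", 0.25, 0)),
        total_lipid_concentration=25.0,
    )


def default_focusing_flows() -> FocusingFlows:
    """11 uL/min lipid stream focused by two 55 uL/min water streams."""
    return FocusingFlows(center_flow=11.0, side_flows=(55.0, 55.0))


def focusing_dilution(mix: LipidMix, flows: FocusingFlows) -> LipidMix:
    """Dilute ``mix`` by the hydrodynamic-focusing flow-rate ratio.

    Every concentration scales by center/(center + sum(sides)); molar
    fractions are unchanged (focusing dilutes, it does not fractionate).
    """
    return replace(
        mix,
        total_lipid_concentration=(
            mix.total_lipid_concentration * flows.dilution_factor
        ),
    )


def snap_to_nominal(
    ratio: float,
    nominal_ratios: tuple[float, ...] = NOMINAL_RATIOS,
    window: float = NOMINAL_SNAP_WINDOW,
) -> float | None:
    """Return the nearest nominal ratio when within ``window`` (relative),
    else None."""
    if not nominal_ratios:
        return None
    nearest = min(nominal_ratios, key=lambda nom: abs(ratio - nom))
    if abs(ratio - nearest) <= window * nearest:
        return nearest
    return None


def charge_ratio(recipe: LipoplexRecipe) -> RatioResult:
    """Molar charge ratio R+/- of a lipoplex preparation.

    Positive charges (nmol) = cationic lipid mM x liposome volume uL;
    negative charges (nmol) = 1000 x pDNA ug / (g/mol per nucleotide).
    """
    if recipe.pdna_mass <= 0:
        raise InvalidInputError("charge ratio undefined for pdna_mass <= 0")
    positive_nmol = recipe.liposome_cationic_concentration * recipe.liposome_volume
    negative_nmol = recipe.pdna_mass * 1000.0 / recipe.nucleotide_mw
    r = positive_nmol / negative_nmol
    return RatioResult(r_plus_minus=r, nominal=snap_to_nominal(r))


def default_recipe(liposome_volume: float) -> LipoplexRecipe:
    """The experiment's preparation: 0.07 ug pDNA + ``liposome_volume`` uL of
    focus-diluted liposomes in 4 uL total."""
    diluted = focusing_dilution(default_lipid_mix(), default_focusing_flows())
    return LipoplexRecipe(
        pdna_mass=7e-2,
        liposome_volume=liposome_volume,
        final_volume=4.0,
        liposome_cationic_concentration=diluted.cationic_concentration,
    )


@dataclass(frozen=True)
class DropletDose:
    """Expected lipoplex count per droplet and its order of magnitude."""

    expected_count: float
    nearest_power_of_ten: float


def lipoplexes_per_droplet(
    particle_concentration: float,
    lipoplex_volume: float,
    total_mix_volume: float,
    droplet_volume: float,
) -> DropletDose:
    """Expected number of lipoplexes co-encapsulated in one droplet.

    Parameters
    ----------
    particle_concentration : particles per uL of the lipoplex preparation.
    lipoplex_volume : uL of lipoplexes added to the loading mix.
    total_mix_volume : uL of the full loading mix (cells + agarose + lipoplexes).
    droplet_volume : droplet volume in nL.
    """
    if total_mix_volume <= 0 or droplet_volume <= 0 or lipoplex_volume < 0:
        raise InvalidInputError("volumes must be positive")
    if particle_concentration < 0:
        raise InvalidInputError("particle concentration must be >= 0")
    count = (
        particle_concentration
        * (lipoplex_volume / total_mix_volume)
        * droplet_volume
        * 1e-3  # nL -> uL
    )
    power = 10.0 ** round(math.log10(count)) if count > 0 else 0.0
    return DropletDose(expected_count=count, nearest_power_of_ten=power)
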
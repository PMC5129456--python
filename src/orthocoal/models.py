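"""Demographic model specification for two-population divergence histories.

The sampling scheme throughout is one unphased diploid genome per taxon, so a
genealogy relates four haploid lineages: ``a1, a2`` from taxon A and ``b1, b2``
from taxon B.  An ancestral population of effective size ``N_anc`` splits at
time ``T`` (in units of ``2 N_anc`` generations, looking back) into descendant
populations A and B.  Four model classes are distinguished:

``Div``
    strict divergence, both descendants at size ``N_anc``;
``IM``
    divergence plus unidirectional migration at rate ``M = 4 N_anc m``
    (effective number of migrant individuals per generation, forward in time
    from donor to recipient), descendants at size ``N_anc``;
``Div2``
    strict divergence with an instantaneous size change in exactly one
    descendant (``N_target = factor x N_anc``);
``IM2``
    both migration and the one-sided size change.

``theta`` is the ancestral per-site scaled mutation rate ``4 N_anc mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: Folded mutation classes for a pair of unphased diploids.
K_A = "kA"  #: heterozygous in taxon A only
K_B = "kB"  #: heterozygous in taxon B only
K_AB = "kAB"  #: heterozygous in both taxa
K_AABB = "kAABB"  #: alternate homozygotes (fixed difference)
CLASSES = (K_A, K_B, K_AB, K_AABB)

MODEL_CLASSES = ("Div", "IM", "Div2", "IM2")

#: Migration directions, written forward in time as donor->recipient.
A_TO_B = "A->B"
B_TO_A = "B->A"


@dataclass(frozen=True)
class DemographicModel:
    """A fully specified two-population divergence/migration model.

    Parameters
    ----------
    model_class:
        One of ``Div``, ``IM``, ``Div2``, ``IM2``.
    theta:
        Ancestral per-site scaled mutation rate, ``4 N_anc mu``.
    T:
        Split time in units of ``2 N_anc`` generations; ``T >= 0``.
    M:
        Scaled migration rate ``4 N_anc m`` (migrant individuals per
        generation), unidirectional.  Must be 0 for ``Div``/``Div2``.
    direction:
        Forward-time direction of migration, ``"A->B"`` or ``"B->A"``.
        Required when ``M > 0``.
    size_factor:
        Ratio of one descendant's effective size to ``N_anc``.  Must be 1
        for ``Div``/``IM``.
    size_target:
        Which descendant (``"A"`` or ``"B"``) carries ``size_factor``.
    """

    model_class: str
    theta: float
    T: float
    M: float = 0.0
    direction: str | None = None
    size_factor: float = 1.0
    size_target: str | None = None

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError("theta must be positive and finite")
        if not (self.T >= 0 and math.isfinite(self.T)):
            raise ValueError("T must be >= 0 and finite")
        if self.M < 0 or not math.isfinite(self.M):
            raise ValueError("M must be >= 0 and finite")
        if self.size_factor <= 0 or not math.isfinite(self.size_factor):
            raise ValueError("size_factor must be positive and finite")
        if self.model_class in ("Div", "Div2") and self.M != 0:
            raise ValueError(f"{self.model_class} requires M = 0")
        if self.model_class in ("Div", "IM") and self.size_factor != 1.0:
            raise ValueError(f"{self.model_class} requires size_factor = 1")
        if self.M > 0 and self.direction not in (A_TO_B, B_TO_A):
            raise ValueError("migration requires direction 'A->B' or 'B->A'")
        if self.size_factor != 1.0 and self.size_target not in ("A", "B"):
            raise ValueError("size change requires size_target 'A' or 'B'")

    # -- convenience -----------------------------------------------------

    def population_size(self, pop: str) -> float:
        """Relative size of population ``pop`` ('A', 'B' or 'ANC')."""
        if pop == "ANC":
            return 1.0
        if self.size_target == pop:
            return self.size_factor
        return 1.0

    @property
    def recipient(self) -> str | None:
        """Forward-time recipient population (lineages there trace back to
        the donor at rate ``M/2`` per ``2 N_anc`` generations)."""
        if self.M == 0 or self.direction is None:
            return None
        return self.direction.split("->")[1]

    @property
    def donor(self) -> str | None:
        if self.M == 0 or self.direction is None:
            return None
        return self.direction.split("->")[0]

    def swapped(self) -> "DemographicModel":
        """The same history with the A/B labels exchanged."""
        direction = None
        if self.direction is not None:
            a, b = self.direction.split("->")
            direction = f"{_swap(a)}->{_swap(b)}"
        target = _swap(self.size_target) if self.size_target else None
        return replace(self, direction=direction, size_target=target)


def _swap(pop: str) -> str:
    return {"A": "B", "B": "A"}[pop]


@dataclass(frozen=True)
class ModelVariant:
    """A model class together with its discrete choices (direction, which
    side carries the size change); the free parameters are fitted."""

    model_class: str
    direction: str | None = None
    size_target: str | None = None

    @property
    def n_params(self) -> int:
        n = 2  # theta, T
        if self.model_class in ("IM", "IM2"):
            n += 1
        if self.model_class in ("Div2", "IM2"):
            n += 1
        return n

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["theta", "T"]
        if self.model_class in ("IM", "IM2"):
            names.append("M")
        if self.model_class in ("Div2", "IM2"):
            names.append("size_factor")
        return tuple(names)

    def label(self) -> str:
        bits = [self.model_class]
        if self.direction:
            bits.append(self.direction)
        if self.size_target:
            bits.append(f"Ne:{self.size_target}")
        return " ".join(bits)

    def bind(self, params: dict[str, float]) -> DemographicModel:
        """Instantiate a :class:`DemographicModel` from fitted parameters."""
        return DemographicModel(
            model_class=self.model_class,
            theta=params["theta"],
            T=params["T"],
            M=params.get("M", 0.0),
            direction=self.direction if self.model_class in ("IM", "IM2") else None,
            size_factor=params.get("size_factor", 1.0),
            size_target=self.size_target if self.model_class in ("Div2", "IM2") else None,
        )


def enumerate_variants(model_classes=MODEL_CLASSES) -> list[ModelVariant]:
    """All discrete variants of the requested model classes: both migration
    directions for IM/IM2 and both size-change targets for Div2/IM2."""
    out: list[ModelVariant] = []
    for mc in model_classes:
        dirs = (A_TO_B, B_TO_A) if mc in ("IM", "IM2") else (None,)
        targets = ("A", "B") if mc in ("Div2", "IM2") else (None,)
        for d in dirs:
            for t in targets:
                out.append(ModelVariant(mc, direction=d, size_target=t))
    return out
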
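"""Clonal tumor architecture and passage dynamics.

A tumor is modeled as a small set of clones, each carrying a set of variants
at known cellular fractions per stage (the patient's primary tumor and mouse
passages P0..P2). Engraftment and serial passage are modeled as a multinomial
bottleneck with optional per-clone selection weights, which is the standard
population-genetic picture behind the observation that minor subclones can
expand during xenograft development. Ground-truth allele fractions for every
planted variant at every stage follow directly from clone fractions, tumor
purity and zygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STAGES = ("primary", "P0", "P1", "P2")

#: read-origin compartments
ORIGIN_TUMOR, ORIGIN_HUMAN_STROMA, ORIGIN_MOUSE_STROMA = 0, 1, 2
ORIGIN_NAMES = ("tumor", "human_stroma", "mouse_stroma")


@dataclass(frozen=True)
class PlantedVariant:
    """A ground-truth variant planted in the simulated tumor.

    ``pos0`` is the 0-based anchor position on the shared toy reference;
    ``ref``/``alt`` follow VCF conventions (left-anchored indels). Germline
    variants are carried by every human cell (tumor and human stroma) and
    carry a population allele frequency used to exercise the germline filter.
    """

    variant_id: str
    pos0: int
    ref: str
    alt: str
    vtype: str  # "SNP" | "indel"
    gene: str | None = None
    is_driver: bool = False
    zygosity: str = "het"  # "het" | "hom"
    germline: bool = False
    pop_af: float | None = None
    contig: str = "chrT_h"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos0 + 1, self.ref, self.alt)

    @property
    def ploidy_factor(self) -> float:
        return 1.0 if self.zygosity == "hom" else 0.5


@dataclass
class Clone:
    """One tumor clone: a variant set and a cellular fraction per stage."""

    clone_id: str
    variant_ids: tuple[str, ...]
    fraction_by_stage: dict[str, float]

    def fraction(self, stage: str) -> float:
        return self.fraction_by_stage[stage]


@dataclass
class ClonalModel:
    """Clones plus stromal composition per stage for one case.

    Invariants: per stage, clone fractions sum to 1 within the tumor-cell
    compartment, and tumor + human-stroma + mouse-stroma read fractions sum
    to 1. Xenograft stages must have strictly less human stroma than the
    primary (engraftment replaces human stroma with mouse stroma).
    """

    case_id: str
    clones: list[Clone]
    variants: list[PlantedVariant]
    stromal_human_fraction: dict[str, float] = field(default_factory=dict)
    stromal_mouse_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {v.variant_id: v for v in self.variants}
        self.validate()

    def validate(self) -> None:
        for stage in self.stages():
            fracs = [c.fraction_by_stage.get(stage, 0.0) for c in self.clones]
            if any(f < 0 or f > 1 for f in fracs):
                raise ValueError(f"clone fractions outside [0,1] at stage {stage}")
            if abs(sum(fracs) - 1.0) > 1e-6:
                raise ValueError(f"clone fractions at stage {stage} do not sum to 1")
            sh = self.stromal_human_fraction.get(stage, 0.0)
            sm = self.stromal_mouse_fraction.get(stage, 0.0)
            tol = 1e-9
            if sh < -tol or sm < -tol or sh + sm > 1 + tol:
                raise ValueError(f"invalid stromal fractions at stage {stage}")
            if stage in self.stromal_human_fraction:
                self.stromal_human_fraction[stage] = max(sh, 0.0)
            if stage in self.stromal_mouse_fraction:
                self.stromal_mouse_fraction[stage] = max(sm, 0.0)
        primary_sh = self.stromal_human_fraction.get("primary")
        if primary_sh is not None:
            for stage in self.stages():
                if stage != "primary" and stage in self.stromal_mouse_fraction:
                    if self.stromal_human_fraction.get(stage, 0.0) >= primary_sh > 0:
                        raise ValueError(
                            "xenograft stage must have less human stroma than primary"
                        )

    def stages(self) -> list[str]:
        seen = set()
        for c in self.clones:
            seen.update(c.fraction_by_stage)
        return [s for s in STAGES if s in seen]

    def variant(self, variant_id: str) -> PlantedVariant:
        return self._by_id[variant_id]

    def tumor_fraction(self, stage: str) -> float:
        """Fraction of reads drawn from tumor cells at this stage (purity)."""
        return 1.0 - self.stromal_human_fraction.get(stage, 0.0) - self.stromal_mouse_fraction.get(stage, 0.0)

    def clone_fractions(self, stage: str) -> np.ndarray:
        return np.array([c.fraction_by_stage.get(stage, 0.0) for c in self.clones])

    def carriers(self, variant_id: str) -> list[int]:
        """Indices of clones carrying the given variant."""
        return [i for i, c in enumerate(self.clones) if variant_id in c.variant_ids]

    def cancer_cell_fraction(self, variant_id: str, stage: str) -> float:
        v = self._by_id[variant_id]
        if v.germline:
            return 1.0
        return float(sum(self.clones[i].fraction_by_stage.get(stage, 0.0) for i in self.carriers(variant_id)))

    def expected_af(self, variant_id: str, stage: str) -> float:
        """Expected allele fraction among all reads covering the site.

        expected_AF = purity x (sum of carrying-clone fractions) x ploidy
        factor (0.5 for heterozygous diploid). Germline variants are carried
        by the whole human compartment (tumor plus human stroma).
        """
        v = self._by_id[variant_id]
        if v.germline:
            human = self.tumor_fraction(stage) + self.stromal_human_fraction.get(stage, 0.0)
            return human * v.ploidy_factor
        return self.tumor_fraction(stage) * self.cancer_cell_fraction(v.variant_id, stage) * v.ploidy_factor


def simulate_passage(
    model: ClonalModel,
    stage_from: str,
    stage_to: str,
    bottleneck_cells: int,
    selection_weights: np.ndarray | list[float] | None = None,
    seed: int = 0,
    stromal_human_fraction: float = 0.0,
    stromal_mouse_fraction: float = 0.1,
) -> ClonalModel:
    """Propagate clone fractions through an engraftment/passage bottleneck.

    ``bottleneck_cells`` cells are drawn multinomially with probabilities
    proportional to (fraction at ``stage_from``) x (selection weight), then
    renormalized to give the clone fractions at ``stage_to``. Neutral passage
    (all weights equal) preserves fractions up to multinomial noise; a weight
    of zero is lethal for the clone. The destination stage is a xenograft by
    default: no human stroma, a configurable mouse-stroma read fraction.
    """
    if bottleneck_cells < 1:
        raise ValueError("bottleneck_cells must be >= 1")
    fracs = model.clone_fractions(stage_from)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"clone fractions at stage {stage_from!r} missing or unnormalized")
    if selection_weights is None:
        weights = np.ones_like(fracs)
    else:
        weights = np.asarray(selection_weights, dtype=float)
        if weights.shape != fracs.shape:
            raise ValueError("one selection weight per clone required")
        if (weights < 0).any():
            raise ValueError("selection weights must be non-negative")
    p = fracs * weights
    total = p.sum()
    if total <= 0:
        raise ValueError("selection eliminated every clone")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(bottleneck_cells), p / total)
    new_fracs = counts / counts.sum()

    new_clones = [
        replace(c, fraction_by_stage={**c.fraction_by_stage, stage_to: float(f)})
        for c, f in zip(model.clones, new_fracs)
    ]
    return ClonalModel(
        case_id=model.case_id,
        clones=new_clones,
        variants=model.variants,
        stromal_human_fraction={**model.stromal_human_fraction, stage_to: stromal_human_fraction},
        stromal_mouse_fraction={**model.stromal_mouse_fraction, stage_to: stromal_mouse_fraction},
    )
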
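"""Experimental conditions: donor genotype plus overexpressed chromatin modifiers."""

from __future__ import annotations

from dataclasses import dataclass, field

GENOTYPES = ("WT", "Dnmt1N", "Ring1abKO")
MODIFIERS = ("Kdm4d", "Kdm6b", "USP21", "Ring1bMut", "dCas9-USP21")


@dataclass(frozen=True)
class Condition:
    """One chromatin configuration tested in the NT reprogramming assay.

    ``genotype`` is the donor-cell genotype (``WT``, DNA-hypomethylated
    ``Dnmt1N``, or ``Ring1abKO``); ``modifiers`` is the (possibly empty) set
    of chromatin-modifier mRNAs overexpressed in the recipient oocyte.
    """

    genotype: str = "WT"
    modifiers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        object.__setattr__(self, "modifiers", frozenset(self.modifiers))
        unknown = self.modifiers - set(MODIFIERS)
        if unknown:
            raise ValueError(f"unknown modifiers {sorted(unknown)}")

    @property
    def label(self) -> str:
        if not self.modifiers:
            return self.genotype
        return self.genotype + "+" + "+".join(sorted(self.modifiers))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def default_panel() -> list[Condition]:
    """The 12-condition treatment panel: two donor genotypes (WT and
    DNA-hypomethylated Dnmt1N fibroblasts) crossed with six modifier sets
    (untreated, Kdm4d, Kdm6b, USP21, USP21+Kdm6b, USP21+Kdm6b+Kdm4d)."""
    modifier_sets = [
        frozenset(),
        frozenset({"Kdm4d"}),
        frozenset({"Kdm6b"}),
        frozenset({"USP21"}),
        frozenset({"USP21", "Kdm6b"}),
        frozenset({"USP21", "Kdm6b", "Kdm4d"}),
    ]
    return [
        Condition(genotype=g, modifiers=m)
        for g in ("WT", "Dnmt1N")
        for m in modifier_sets
    ]
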
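"""A compact CATAMI-style hierarchical vocabulary for benthic image annotation.

CATAMI organizes what an annotator sees under a point into a tree whose depth
encodes coarseness: here level 3 is the kingdom-ish split (biota vs physical
substrate), level 4 the broad biological group (sponges, bryozoa, ...), and
levels 5–6 progressively finer morphotypes.  Codes are slash-separated paths
("biota/sponges/massive"); the level of a code is its path depth plus 2, so
"biota/sponges" sits at level 4.

The table shipped here is a small, editable stand-in covering the groups that
dominate temperate shelf reefs — it is not the full official scheme, and can
be replaced wholesale via :class:`Vocabulary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Vocabulary", "default_vocabulary", "BIOTA_GROUPS", "LEVEL_OFFSET"]

#: path depth 1 ("biota") corresponds to CATAMI level 3
LEVEL_OFFSET = 2

#: level-4 biological groups reported in shelf baseline tables
BIOTA_GROUPS = (
    "biota/ascidians",
    "biota/bryozoa",
    "biota/cnidaria",
    "biota/echinoderms",
    "biota/macroalgae",
    "biota/molluscs",
    "biota/sponges",
)

_DEFAULT_LEAVES = (
    # biota: level-6 leaves (group / morphology / form)
    "biota/ascidians/stalked/solitary",
    "biota/ascidians/unstalked/solitary",
    "biota/ascidians/unstalked/colonial",
    "biota/bryozoa/hard/fenestrate",
    "biota/bryozoa/hard/non_fenestrate",
    "biota/bryozoa/soft/dendroid",
    "biota/cnidaria/corals/soft_coral",
    "biota/cnidaria/corals/black_octocoral",
    "biota/cnidaria/hydroids/hydroid",
    "biota/echinoderms/sea_stars/asteroid",
    "biota/echinoderms/urchins/regular",
    "biota/macroalgae/erect_coarse/brown",
    "biota/macroalgae/erect_fine/red",
    "biota/macroalgae/encrusting/calcareous",
    "biota/molluscs/bivalves/attached",
    "biota/molluscs/gastropods/grazing",
    "biota/sponges/massive/simple",
    "biota/sponges/erect/branching",
    "biota/sponges/encrusting/thin",
    # physical substrate (no biota under the point)
    "substrate/consolidated/rock",
    "substrate/consolidated/boulders",
    "substrate/consolidated/cobbles",
    "substrate/unconsolidated/sand",
    "substrate/unconsolidated/mud",
)


@dataclass
class Vocabulary:
    """An editable hierarchical code table with level-indexed prefixes."""

    leaves: tuple[str, ...] = _DEFAULT_LEAVES
    _codes: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for leaf in self.leaves:
            parts = leaf.split("/")
            for i in range(1, len(parts) + 1):
                self._codes.add("/".join(parts[:i]))

    @staticmethod
    def level_of(code: str) -> int:
        return code.count("/") + 1 + LEVEL_OFFSET

    def validate(self, code: str) -> None:
        if code not in self._codes:
            known = ", ".join(sorted(self.leaves))
            raise ValueError(f"unknown label {code!r}; known leaves: {known}")

    def codes_at_level(self, level: int, biota_only: bool = True) -> list[str]:
        out = sorted(
            c
            for c in self._codes
            if self.level_of(c) == level
            and (not biota_only or c.startswith("biota/"))
        )
        return out

    def ancestor_at_level(self, code: str, level: int) -> str | None:
        """Truncate a code to the requested level; None if the code is coarser
        than the level or is not a biota code."""
        self.validate(code)
        if not code.startswith("biota/"):
            return None
        depth = level - LEVEL_OFFSET  # path components at that level
        parts = code.split("/")
        if len(parts) < depth:
            return None
        return "/".join(parts[:depth])


def default_vocabulary() -> Vocabulary:
    return Vocabulary()
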
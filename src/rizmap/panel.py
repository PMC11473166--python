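"""Zone marker panels.

A :class:`ZonePanel` carries one ordered marker gene set per concentric zone of
a regenerative inflammation zone (RIZ):

* zone ``A`` — damage-clearing lesion core (Langhans giant cells; *Ccl7*,
  *Ccl2*, *Il1rn*),
* zone ``B`` — resolution / growth-factor-expressing macrophage barrier
  (*Mmp12*, *Nckap1l*, *Itgb2*, *Atf3*),
* zone ``C`` — regenerating periphery of newly formed myofibers (*Myh3*,
  *Myog*, *Myl4*).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InvalidConfigurationError

#: Canonical zone labels, inside-out.
ZONES: tuple[str, ...] = ("A", "B", "C")

#: Label used for spots/points that belong to no zone.
NO_ZONE: str = "none"

#: Default marker panel (mouse symbols).
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "A": ("Ccl7", "Ccl2", "Il1rn"),
    "B": ("Mmp12", "Nckap1l", "Itgb2", "Atf3"),
    "C": ("Myh3", "Myog", "Myl4"),
}


@dataclasses.dataclass(frozen=True)
class ZonePanel:
    """Ordered marker gene sets for zones A, B and C.

    Parameters
    ----------
    markers
        Mapping zone label -> ordered tuple of gene symbols. Every zone in
        :data:`ZONES` must be present with a non-empty, pairwise-disjoint set.
    """

    markers: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        markers = {z: tuple(g) for z, g in self.markers.items()}
        object.__setattr__(self, "markers", markers)
        if tuple(markers) != ZONES:
            raise InvalidConfigurationError(
                f"panel must define zones {ZONES} in order, got {tuple(markers)}"
            )
        seen: dict[str, str] = {}
        for zone, genes in markers.items():
            if not genes:
                raise InvalidConfigurationError(f"zone {zone!r} marker set is empty")
            for g in genes:
                if g in seen:
                    raise InvalidConfigurationError(
                        f"gene {g!r} appears in zones {seen[g]!r} and {zone!r}; "
                        "marker sets must be disjoint"
                    )
                seen[g] = zone

    @classmethod
    def default(cls) -> "ZonePanel":
        return cls(dict(DEFAULT_MARKERS))

    @classmethod
    def with_size(cls, n_per_zone: int) -> "ZonePanel":
        """Panel with ``n_per_zone`` markers per zone.

        The canonical symbols are used first; synthetic symbols
        (``<gene>Sim<zone><i>``) pad larger panels. Used by the tissue
        simulator when a non-default panel size is requested.
        """
        if n_per_zone < 1:
            raise InvalidConfigurationError("n_per_zone must be >= 1")
        markers = {}
        for zone in ZONES:
            canon = DEFAULT_MARKERS[zone]
            genes = list(canon[:n_per_zone])
            genes += [f"Sim{zone}{i:02d}" for i in range(len(genes), n_per_zone)]
            markers[zone] = tuple(genes)
        return cls(markers)

    @property
    def zones(self) -> tuple[str, ...]:
        return ZONES

    @property
    def genes(self) -> list[str]:
        """All panel genes, zone A first, in panel order."""
        return [g for z in ZONES for g in self.markers[z]]

    def zone_of(self) -> dict[str, str]:
        """Mapping gene symbol -> zone label."""
        return {g: z for z in ZONES for g in self.markers[z]}

    def __getitem__(self, zone: str) -> tuple[str, ...]:
        return self.markers[zone]


def read_panel(path: str | Path) -> ZonePanel:
    """Read a panel file: one ``[zone]`` header per block, one symbol per line.

    Blank lines and ``#`` comments are ignored.
    """
    markers: dict[str, list[str]] = {}
    current: list[str] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            zone = line[1:-1].strip()
            current = markers.setdefault(zone, [])
        elif current is None:
            raise InvalidConfigurationError(
                f"{path}:{lineno}: gene symbol before any [zone] header"
            )
        else:
            current.append(line)
    ordered = {z: tuple(markers.get(z, ())) for z in ZONES}
    return ZonePanel(ordered)


def write_panel(panel: ZonePanel, path: str | Path) -> None:
    lines: list[str] = []
    for zone in panel.zones:
        lines.append(f"[{zone}]")
        lines.extend(panel[zone])
    Path(path).write_text("\n".join(lines) + "\n")


def match_genes(
    requested: Iterable[str], available: Iterable[str], case_insensitive: bool = False
) -> list[str]:
    """Return the requested symbols present in ``available`` (order kept).

    With ``case_insensitive`` the match ignores case but the returned symbols
    are the ones spelled as in ``available`` (mouse vs human casing).
    """
    if case_insensitive:
        lookup = {a.lower(): a for a in available}
        return [lookup[r.lower()] for r in requested if r.lower() in lookup]
    pool = set(available)
    return [r for r in requested if r in pool]
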
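"""Six-level protein-target class hierarchy.

Drug targets are organised in a curated family hierarchy of six levels,
L1 (broadest, e.g. "Enzyme") down to L6 (most specific). The hierarchy is a
tree rooted at a virtual root node above L1; each target is attached to
exactly one leaf. Distances between targets are shortest paths in this tree,
so two full-depth leaves in different L1 classes are 12 edges apart
(6 up to the root, 6 down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

N_LEVELS = 6


@dataclass
class ClassHierarchy:
    """A populated class tree plus the leaf each target hangs from.

    Parameters
    ----------
    leaves : list of tuple of str
        Every leaf as its full path of ``N_LEVELS`` labels from L1 to L6.
    target_paths : dict
        Maps ``target_id`` to the leaf path the target is attached to.
    """

    leaves: list[tuple[str, ...]]
    target_paths: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for leaf in self.leaves:
            if len(leaf) != N_LEVELS:
                raise ValueError(f"leaf {leaf!r} does not have {N_LEVELS} levels")
        leafset = set(self.leaves)
        for tid, path in self.target_paths.items():
            if tuple(path) not in leafset:
                raise ValueError(f"target {tid!r} attached to unknown leaf {path!r}")

    def attach(self, target_id: str, leaf: tuple[str, ...]) -> None:
        if tuple(leaf) not in set(self.leaves):
            raise ValueError(f"unknown leaf {leaf!r}")
        self.target_paths[target_id] = tuple(leaf)

    def path_of(self, target_id: str) -> tuple[str, ...]:
        try:
            return self.target_paths[target_id]
        except KeyError:
            raise KeyError(f"target {target_id!r} is not attached to the hierarchy")

    def node_distance(self, path_a: tuple[str, ...], path_b: tuple[str, ...]) -> int:
        """Shortest path (edge count) between two nodes given as label paths.

        A node is identified by its path prefix; the virtual root is the
        empty path. The unique tree path climbs to the deepest common
        ancestor and descends again.
        """
        a, b = tuple(path_a), tuple(path_b)
        common = 0
        for la, lb in zip(a, b):
            if la != lb:
                break
            common += 1
        return (len(a) - common) + (len(b) - common)

    def tree_distance(self, target_a: str, target_b: str) -> int:
        """Shortest-path distance between the leaves of two targets."""
        return self.node_distance(self.path_of(target_a), self.path_of(target_b))

    def level_labels(self, level: int) -> list[str]:
        """Distinct labels at 1-based level ``level``, in leaf order."""
        seen: dict[str, None] = {}
        for leaf in self.leaves:
            seen.setdefault(leaf[level - 1], None)
        return list(seen)

    # -- serialization --------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "leaves": [list(p) for p in self.leaves],
            "target_paths": {t: list(p) for t, p in self.target_paths.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassHierarchy":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            leaves=[tuple(p) for p in payload["leaves"]],
            target_paths={t: tuple(p) for t, p in payload["target_paths"].items()},
        )


def preferred_name_groups(names: dict[str, str]) -> dict[str, list[str]]:
    """Group targets sharing a curated preferred name.

    Only groups with two or more members are reported; singleton names stay
    usable as per-target features but carry no grouping information.

    Parameters
    ----------
    names : dict
        Maps target_id to its preferred name.

    Returns
    -------
    dict
        Maps preferred name to the sorted list of member target ids, for
        names shared by at least two targets.
    """
    by_name: dict[str, list[str]] = {}
    for tid, name in names.items():
        by_name.setdefault(name, []).append(tid)
    return {name: sorted(tids) for name, tids in by_name.items() if len(tids) >= 2}
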
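"""Random speaker groups with twin-pair exclusion, and test-pair enumeration.

Comparisons are run inside random groups of speakers chosen so that no two
group members are twin siblings — twin-vs-twin trials are atypically hard
and are excluded from both the tested pairs and the background population.
With 20 speakers forming 10 twin pairs and groups of 10, the constraint
forces exactly one member per pair, so the canonical construction is a fair
coin per pair. Groups are sampled with replacement (duplicates permitted):
the requested number of groups may exceed the number of distinct feasible
groups under other configurations.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

__all__ = ["SpeakerGroup", "make_groups", "enumerate_pairs", "GroupingError"]

_REJECTION_CAP = 10_000


class GroupingError(ValueError):
    """The requested grouping is infeasible under the twin-exclusion constraint."""


@dataclass(frozen=True)
class SpeakerGroup:
    group_id: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))


def make_groups(
    speakers: Iterable[str],
    twin_map: Mapping[str, str | None],
    n_groups: int = 150,
    group_size: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SpeakerGroup]:
    """Sample ``n_groups`` twin-free groups of ``group_size`` speakers.

    In the canonical fully paired case (every speaker twinned, group size =
    number of pairs) one member of each pair is chosen by an independent
    fair coin. Otherwise groups are drawn by rejection sampling over
    ``group_size``-subsets, capped at 10^4 attempts per group.
    """
    speakers = sorted(speakers)
    if rng is None:
        rng = np.random.default_rng(seed)
    if group_size > len(speakers):
        raise GroupingError("group_size exceeds the number of speakers")
    # distinct "units" (pairs + singletons) bound the largest twin-free group
    unit_ids = {s: twin_map.get(s) if twin_map.get(s) is not None else ("solo", s) for s in speakers}
    if group_size > len(set(unit_ids.values())):
        raise GroupingError(
            f"no twin-free group of size {group_size} exists "
            f"({len(set(unit_ids.values()))} distinct twin units)"
        )

    pairs: dict[str, list[str]] = {}
    for s in speakers:
        p = twin_map.get(s)
        if p is not None:
            pairs.setdefault(p, []).append(s)
    fully_paired = (
        all(len(m) == 2 for m in pairs.values())
        and 2 * len(pairs) == len(speakers)
        and group_size == len(pairs)
    )

    groups: list[SpeakerGroup] = []
    if fully_paired:
        pair_ids = sorted(pairs)
        for gid in range(n_groups):
            coins = rng.integers(0, 2, size=len(pair_ids))
            members = tuple(pairs[p][c] for p, c in zip(pair_ids, coins))
            groups.append(SpeakerGroup(gid, members))
        return groups

    for gid in range(n_groups):
        for _ in range(_REJECTION_CAP):
            chosen = rng.choice(len(speakers), size=group_size, replace=False)
            members = [speakers[i] for i in chosen]
            units = {unit_ids[s] for s in members}
            if len(units) == group_size:
                groups.append(SpeakerGroup(gid, tuple(members)))
                break
        else:
            raise GroupingError(
                f"could not draw a twin-free group of size {group_size} "
                f"in {_REJECTION_CAP} attempts"
            )
    return groups


def enumerate_pairs(group: SpeakerGroup) -> list[tuple[str, str]]:
    """All C(n, 2) unordered member pairs in lexicographic order."""
    if len(group.members) < 2:
        raise ValueError("need at least 2 members to enumerate pairs")
    return list(itertools.combinations(sorted(group.members), 2))
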
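"""Activity-profile rank-score encodings.

A compound screened against m targets has a binary activity profile
(y_1, ..., y_m).  For ranking, profiles are mapped to integer rank
scores s >= 0: the desired profile (active on every main target, on
nothing else) gets the unique maximum, graded deviations get lower
scores, and decoys get 0.  The builder generalizes the canonical
three-target schemes (single main target; dual main targets; single
main with ordered secondary avoidance; dual mains with ordered main
priority) to arbitrary m; the m=3 schemes are pinned by golden tests.

Also provided: the three-level S RANK selectivity labeling
(selective 1 / decoy 0 / non-selective -1) and the plain binary
main-target labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

ActivityProfile = tuple[int, ...]


def _check_profile(p: Sequence[int], m: int) -> ActivityProfile:
    p = tuple(int(v) for v in p)
    if len(p) != m:
        raise ValueError(f"profile length {len(p)} != m={m}")
    if any(v not in (0, 1) for v in p):
        raise ValueError(f"profile values must be 0/1, got {p}")
    return p


@dataclass(frozen=True)
class EncodingScheme:
    """A total map from activity profiles to integer rank scores."""

    m: int
    main_targets: tuple[int, ...]
    secondary_priority: str | tuple[int, ...]
    main_priority: str | tuple[int, ...]
    nonselective_as_decoy: bool
    table: dict[ActivityProfile, int] = field(compare=False)

    @property
    def max_score(self) -> int:
        return max(self.table.values())

    @property
    def desired_profile(self) -> ActivityProfile:
        return tuple(1 if k in self.main_targets else 0 for k in range(self.m))


def _priority_weights(ordered: Sequence[int], pool: Iterable[int]) -> dict[int, int]:
    # first listed = most important; power-of-two weights keep the order
    # of any two severity sets consistent with the listed priorities
    weights = {t: 1 for t in pool}
    for pos, t in enumerate(ordered):
        weights[t] = 2 ** (len(ordered) - pos)
    return weights


def build_scheme(
    m: int,
    main_targets: Iterable[int],
    secondary_priority: str | Sequence[int] = "equal",
    main_priority: str | Sequence[int] = "equal",
    nonselective_as_decoy: bool = False,
) -> EncodingScheme:
    """Build the graded-penalty score table over all 2^m profiles.

    Hard decoy rules (score 0): no main target active; main targets
    incompletely met while any secondary target is hit; and, when
    ``nonselective_as_decoy``, activity on *every* secondary target.
    Remaining profiles are ranked by how far they deviate from the
    desired profile - unwanted secondary activity weighs before missing
    main activity, each aggregated with the stated priorities - and
    equally-deviating profiles share one score, so scores form the
    contiguous range 0..max.
    """
    mains = tuple(sorted(set(int(t) for t in main_targets)))
    if not mains:
        raise ValueError("main_targets must be non-empty")
    if mains[0] < 0 or mains[-1] >= m:
        raise ValueError(f"main target index out of range for m={m}")
    secondaries = tuple(t for t in range(m) if t not in mains)
    if isinstance(secondary_priority, str):
        if secondary_priority != "equal":
            raise ValueError("secondary_priority must be 'equal' or an index list")
        sec_weights = {t: 1 for t in secondaries}
    else:
        listed = tuple(int(t) for t in secondary_priority)
        if set(listed) & set(mains):
            raise ValueError("secondary priority list names a main target")
        if not set(listed) <= set(secondaries):
            raise ValueError("secondary priority list names an unknown target")
        sec_weights = _priority_weights(listed, secondaries)
    if isinstance(main_priority, str):
        if main_priority != "equal":
            raise ValueError("main_priority must be 'equal' or an index list")
        main_weights = {t: 1 for t in mains}
    else:
        listed = tuple(int(t) for t in main_priority)
        if not set(listed) <= set(mains):
            raise ValueError("main priority list must name main targets")
        main_weights = _priority_weights(listed, mains)

    severities: dict[ActivityProfile, tuple[int, int]] = {}
    for profile in product((0, 1), repeat=m):
        hits = [t for t in mains if profile[t]]
        extras = [t for t in secondaries if profile[t]]
        is_decoy = (
            not hits
            or (len(hits) < len(mains) and extras)
            or (nonselective_as_decoy and secondaries
                and len(extras) == len(secondaries))
        )
        if is_decoy:
            continue
        extra_sev = sum(sec_weights[t] for t in extras)
        miss_sev = sum(main_weights[t] for t in mains if not profile[t])
        severities[profile] = (extra_sev, miss_sev)

    tiers = sorted(set(severities.values()))
    table = {p: 0 for p in product((0, 1), repeat=m)}
    for profile, sev in severities.items():
        table[profile] = len(tiers) - tiers.index(sev)
    return EncodingScheme(
        m=m,
        main_targets=mains,
        secondary_priority=(
            "equal" if isinstance(secondary_priority, str)
            else tuple(int(t) for t in secondary_priority)
        ),
        main_priority=(
            "equal" if isinstance(main_priority, str)
            else tuple(int(t) for t in main_priority)
        ),
        nonselective_as_decoy=nonselective_as_decoy,
        table=table,
    )


def encode_profile(scheme: EncodingScheme, p: Sequence[int]) -> int:
    """Rank score of a profile under a scheme (total table lookup)."""
    return scheme.table[_check_profile(p, scheme.m)]


def srank_encode(p: Sequence[int], main: int) -> int:
    """Three-level selectivity label: selective 1, decoy 0, non-selective -1."""
    p = _check_profile(p, len(p))
    if not p[main]:
        return 0
    if sum(p) > 1:
        return -1
    return 1


def binary_labels(p: Sequence[int], main_targets: Iterable[int]) -> int:
    """1 iff active on all main targets (other targets ignored)."""
    mains = tuple(set(int(t) for t in main_targets))
    if not mains:
        raise ValueError("main_targets must be non-empty")
    p = _check_profile(p, len(p))
    return int(all(p[t] for t in mains))


def drop_promiscuous(
    profiles: Sequence[Sequence[int]],
) -> list[int]:
    """Indices of compounds NOT active on all m targets (optional pre-filter).

    Highly promiscuous compounds can interfere with similarity-based
    models; this helper keeps everything except the all-active profile.
    """
    kept = []
    for i, p in enumerate(profiles):
        if sum(p) < len(p):
            kept.append(i)
    return kept
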
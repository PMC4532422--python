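"""Systematic-artifact flagging and exclusion for cohort-wide call sets.

Phantom mutations are sequencing artifacts that recur across many samples at
low heteroplasmy levels, often sharing a local sequence motif, sometimes with a
one-strand coverage drop at the affected position and with satellite positions
whose apparent levels track the anchor position across samples.  The filters
here encode those signatures:

``phantom_context``
    a position called at low level in many samples; flagged positions sharing
    an identical flanking k-mer are grouped together.
``strand_drop``
    coverage on one strand falls relative to the flanking median while the
    other strand stays flat.
``correlated_neighbor``
    a near-adjacent position whose levels are strongly correlated with, and
    restricted to, samples positive for an anchor position.
``primer_zone`` / ``circular_edge``
    fixed exclusion zones around long-range-PCR primer annealing sites and the
    circular origin.

Filtering is non-destructive: every input call ends up in exactly one of the
pass or excluded sets, with its flags attached.  A high-level call at a
phantom-context position is kept — only calls at or below the low-level bound
are excluded by that flag.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import yaml

from .caller import HeteroplasmyCall
from .errors import ConfigError
from .pileup import FORWARD, REVERSE, Pileup
from .reference import GENOME_LENGTH, MitoGenome

CallsBySample = Mapping[str, Sequence[HeteroplasmyCall]]


@dataclass(frozen=True)
class ExclusionZone:
    start: int
    end: int
    reason: str = "primer_zone"


@dataclass
class ArtifactFlag:
    position: int
    flag_kind: str  # phantom_context | strand_drop | correlated_neighbor | primer_zone | circular_edge
    evidence: dict = field(default_factory=dict)
    affected_samples: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the artifact filters.

    Defaults envelope the observed artifact instances: recurrence in >=8
    samples at <=5% level, a 9-mer shared context, a forward-strand coverage
    drop to <=0.8 of the flanking median with the reverse strand >=0.9 stable,
    a 0.9 correlation bound for satellite positions, a 5-bp circular-edge
    margin and one primer zone at 2523-2667.
    """

    min_samples: int = 8
    max_level_pct: float = 5.0
    context_window: int = 9
    drop_window: int = 5
    drop_ratio_max: float = 0.8
    stable_ratio_min: float = 0.9
    correlation_min: float = 0.9
    neighbor_distance: int = 3
    edge_margin: int = 5
    zones: tuple[tuple[int, int], ...] = ((2523, 2667),)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown filter option(s): {sorted(unknown)}")
        if "zones" in raw:
            raw["zones"] = tuple(tuple(z) for z in raw["zones"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def flag_recurrent_context(
    calls_by_sample: CallsBySample,
    genome: MitoGenome | str,
    min_samples: int = FilterConfig.min_samples,
    max_level_pct: float = FilterConfig.max_level_pct,
    context_window: int = FilterConfig.context_window,
) -> list[ArtifactFlag]:
    """Flag positions recurrently called at low level across samples.

    Only calls with ``minor_pct <= max_level_pct`` count toward recurrence.
    Flagged positions sharing an identical bracketed flanking k-mer are
    reported as one context group (``context_group`` in the evidence).
    """
    if isinstance(genome, str):
        genome = MitoGenome(genome)
    low_samples: dict[int, list[str]] = {}
    low_levels: dict[int, list[float]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            if call.minor_pct <= max_level_pct:
                low_samples.setdefault(call.position, []).append(sample)
                low_levels.setdefault(call.position, []).append(call.minor_pct)
    flags = []
    for position in sorted(low_samples):
        samples = sorted(set(low_samples[position]))
        if len(samples) < min_samples:
            continue
        context = genome.context(position, context_window)
        flags.append(ArtifactFlag(
            position=position,
            flag_kind="phantom_context",
            evidence={
                "recurrence": len(samples),
                "mean_minor_pct": float(np.mean(low_levels[position])),
                "context": context,
            },
            affected_samples=samples,
        ))
    groups: dict[str, list[ArtifactFlag]] = {}
    for flag in flags:
        groups.setdefault(flag.evidence["context"], []).append(flag)
    for gid, (context, members) in enumerate(sorted(groups.items())):
        for flag in members:
            flag.evidence["context_group"] = gid
            flag.evidence["context_group_size"] = len(members)
    return flags


def strand_coverage_drop(
    pileup: Pileup,
    position: int,
    window: int = FilterConfig.drop_window,
    drop_ratio_max: float = FilterConfig.drop_ratio_max,
    stable_ratio_min: float = FilterConfig.stable_ratio_min,
) -> ArtifactFlag | None:
    """Flag a one-strand coverage drop at ``position``.

    The per-strand depth at the position is divided by the median depth of the
    flanking window (``window`` positions each side, circular).  A flag is
    raised when one strand's ratio falls to ``drop_ratio_max`` or below while
    the other strand stays at ``stable_ratio_min`` or above.
    """
    if window < 3:
        raise ValueError("flanking window must contain >=3 positions per side")
    L = pileup.length
    flank = [
        (position - 1 + d) % L for d in range(-window, window + 1) if d != 0
    ]
    ratios = {}
    truncated = False
    for strand in (FORWARD, REVERSE):
        depths = pileup.depth(strand)
        flank_depths = [int(depths[i]) for i in flank if depths[i] > 0]
        if len(flank_depths) < 6:  # fewer than 3 usable flanking sites per side
            truncated = True
        if not flank_depths:
            return None
        med = statistics.median(flank_depths)
        ratios[strand] = float(depths[position - 1]) / med if med else float("inf")
    dropped = [s for s in ratios if ratios[s] <= drop_ratio_max]
    stable = [s for s in ratios if ratios[s] >= stable_ratio_min]
    for strand in dropped:
        other = REVERSE if strand == FORWARD else FORWARD
        if other in stable:
            evidence = {
                "ratio_forward": ratios[FORWARD],
                "ratio_reverse": ratios[REVERSE],
                "dropped_strand": strand,
            }
            if truncated:
                evidence["warning"] = "flanking window truncated"
            return ArtifactFlag(position=position, flag_kind="strand_drop",
                                evidence=evidence)
    return None


def correlated_neighbors(
    calls_by_sample: CallsBySample,
    anchor: int,
    neighbors: Sequence[int] | None = None,
    correlation_min: float = FilterConfig.correlation_min,
    neighbor_distance: int = FilterConfig.neighbor_distance,
) -> tuple[list[ArtifactFlag], list[str]]:
    """Flag satellite positions riding on an anchor artifact position.

    A neighbor is flagged when it occurs only in anchor-positive samples and
    its levels across those samples correlate with the anchor levels above
    ``correlation_min``.  Returns ``(flags, notes)`` where notes record
    indeterminate neighbors (fewer than 3 paired observations, or zero
    variance).
    """
    level_at: dict[int, dict[str, float]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            level_at.setdefault(call.position, {})[sample] = call.level_pct
    anchor_levels = level_at.get(anchor, {})
    notes: list[str] = []
    if len(anchor_levels) < 3:
        notes.append(f"anchor {anchor}: fewer than 3 samples with levels")
        return [], notes
    if neighbors is None:
        neighbors = [
            p for p in level_at
            if p != anchor and abs(p - anchor) <= neighbor_distance
        ]
    flags = []
    for pos in sorted(neighbors):
        samples = level_at.get(pos, {})
        if not samples:
            continue
        outside = set(samples) - set(anchor_levels)
        if outside:
            notes.append(
                f"neighbor {pos}: present in anchor-negative sample(s), not flagged"
            )
            continue
        paired = sorted(samples)
        if len(paired) < 3:
            notes.append(f"neighbor {pos}: only {len(paired)} paired observations")
            continue
        x = np.array([anchor_levels[s] for s in paired])
        y = np.array([samples[s] for s in paired])
        if x.std() == 0 or y.std() == 0:
            notes.append(f"neighbor {pos}: zero variance, correlation undefined")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r >= correlation_min:
            flags.append(ArtifactFlag(
                position=pos,
                flag_kind="correlated_neighbor",
                evidence={"anchor": anchor, "pearson_r": r, "n": len(paired)},
                affected_samples=paired,
            ))
    return flags, notes


def zone_exclusion(
    calls_by_sample: CallsBySample,
    zones: Sequence[tuple[int, int]] = FilterConfig.zones,
    edge_margin: int = FilterConfig.edge_margin,
) -> list[ArtifactFlag]:
    """Flag calls inside primer zones or within the circular-edge margin."""
    zone_objs = [ExclusionZone(start=min(z), end=max(z)) for z in zones]
    flagged: dict[tuple[int, str], ArtifactFlag] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            pos = call.position
            for zone in zone_objs:
                if zone.start <= pos <= zone.end:
                    key = (pos, "primer_zone")
                    flag = flagged.setdefault(key, ArtifactFlag(
                        position=pos, flag_kind="primer_zone",
                        evidence={"zone": (zone.start, zone.end)},
                    ))
                    flag.affected_samples.append(sample)
            if pos <= edge_margin or pos > GENOME_LENGTH - edge_margin:
                key = (pos, "circular_edge")
                flag = flagged.setdefault(key, ArtifactFlag(
                    position=pos, flag_kind="circular_edge",
                    evidence={"edge_margin": edge_margin},
                ))
                flag.affected_samples.append(sample)
    return [flagged[k] for k in sorted(flagged)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    passed: dict[str, list[HeteroplasmyCall]]
    excluded: dict[str, list[HeteroplasmyCall]]
    flags: list[ArtifactFlag]
    audit: dict


def apply_filters(
    calls_by_sample: CallsBySample,
    pileups: Mapping[str, Pileup] | None = None,
    genome: MitoGenome | str | None = None,
    config: FilterConfig = FilterConfig(),
) -> FilterResult:
    """Run all artifact filters in order context -> strand drop -> correlated
    neighbors -> zones, and partition the calls into pass/excluded sets.

    Exclusion rules: ``phantom_context`` and ``strand_drop`` exclude only calls
    at or below ``max_level_pct`` (high-level calls at the same position are
    retained, flags attached); ``correlated_neighbor``, ``primer_zone`` and
    ``circular_edge`` exclude outright.  Without a genome the context filter
    is skipped; without pileups the strand-drop filter is skipped.
    """
    all_flags: list[ArtifactFlag] = []
    notes: list[str] = []
    flag_at: dict[int, list[ArtifactFlag]] = {}

    def add(flags: Sequence[ArtifactFlag]) -> None:
        for flag in flags:
            all_flags.append(flag)
            flag_at.setdefault(flag.position, []).append(flag)

    context_flags: list[ArtifactFlag] = []
    if genome is not None:
        context_flags = flag_recurrent_context(
            calls_by_sample, genome,
            min_samples=config.min_samples,
            max_level_pct=config.max_level_pct,
            context_window=config.context_window,
        )
        add(context_flags)
    if pileups is not None:
        call_positions = sorted({
            c.position for calls in calls_by_sample.values() for c in calls
        })
        for sample, pileup in pileups.items():
            for pos in call_positions:
                flag = strand_coverage_drop(
                    pileup, pos,
                    window=config.drop_window,
                    drop_ratio_max=config.drop_ratio_max,
                    stable_ratio_min=config.stable_ratio_min,
                )
                if flag is not None:
                    flag.affected_samples.append(sample)
                    add([flag])
    for anchor_flag in context_flags:
        nb_flags, nb_notes = correlated_neighbors(
            calls_by_sample, anchor_flag.position,
            correlation_min=config.correlation_min,
            neighbor_distance=config.neighbor_distance,
        )
        add(nb_flags)
        notes.extend(nb_notes)
    add(zone_exclusion(calls_by_sample, zones=config.zones,
                       edge_margin=config.edge_margin))

    low_only_kinds = {"phantom_context", "strand_drop"}
    hard_kinds = {"correlated_neighbor", "primer_zone", "circular_edge"}
    passed: dict[str, list[HeteroplasmyCall]] = {}
    excluded: dict[str, list[HeteroplasmyCall]] = {}
    excluded_by_kind: dict[str, int] = {}
    for sample, calls in calls_by_sample.items():
        passed[sample] = []
        excluded[sample] = []
        for call in calls:
            reasons = set()
            for flag in flag_at.get(call.position, []):
                # strand-drop evidence comes from one sample's pileup and only
                # applies there; the other flag kinds are positional
                if flag.flag_kind == "strand_drop" and \
                        flag.affected_samples and sample not in flag.affected_samples:
                    continue
                if flag.flag_kind in hard_kinds:
                    reasons.add(flag.flag_kind)
                elif flag.flag_kind in low_only_kinds and call.minor_pct <= config.max_level_pct:
                    reasons.add(flag.flag_kind)
                call.filter_flags.add(flag.flag_kind)
            if reasons:
                excluded[sample].append(call)
                for kind in reasons:
                    excluded_by_kind[kind] = excluded_by_kind.get(kind, 0) + 1
            else:
                passed[sample].append(call)
    flag_counts: dict[str, int] = {}
    for flag in all_flags:
        flag_counts[flag.flag_kind] = flag_counts.get(flag.flag_kind, 0) + 1
    audit = {
        "flags_by_kind": flag_counts,
        "excluded_by_kind": excluded_by_kind,
        "n_pass": sum(len(v) for v in passed.values()),
        "n_excluded": sum(len(v) for v in excluded.values()),
        "notes": notes,
    }
    return FilterResult(passed=passed, excluded=excluded, flags=all_flags, audit=audit)
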
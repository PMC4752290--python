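"""Regional aggregation and interhemispheric symmetry of per-channel HFD.

Channels of the 19-channel 10-20 montage are grouped into five regions
per hemisphere; regional HFD is the arithmetic mean over the grouped
channels and the whole-brain value averages every channel in the
recording (midline included by default).

The homologous-areas interhemispheric symmetry index is

    HArS = (HFD_left - HFD_right) / (HFD_left + HFD_right)

computed per homologous channel pair and averaged within a region:
positive values mean left-higher-than-right complexity.  For HFD bounded
in [1, 2] the index is bounded in [-1/3, 1/3].

Two region maps ship with the package.  The default map follows the
channel grouping used in the ageing/AD study verbatim: its temporal-left
region is T5 (= P7), a channel that also belongs to parietal-left, while
temporal-right is T4 (= T8) — an asymmetric, overlapping assignment.  The
``strict_disjoint_region_map`` alternative assigns temporal = (T7, T8),
making regions disjoint and anatomically paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .preprocessing import normalize_label

__all__ = [
    "REGIONS",
    "RegionMap",
    "default_region_map",
    "strict_disjoint_region_map",
    "GENERATOR_REGION_OF_CHANNEL",
    "RegionalProfile",
    "HArSProfile",
    "regional_means",
    "hars",
    "regional_hars",
]

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")


@dataclass(frozen=True)
class RegionMap:
    """Region -> (left channels, right channels), positionally paired.

    The i-th left channel is the homologue of the i-th right channel, so
    the two lists of a region must have equal length.
    """

    pairs: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]]
    name: str = "custom"

    def __post_init__(self) -> None:
        for region, (left, right) in self.pairs.items():
            if len(left) != len(right):
                raise ValueError(
                    f"region {region!r}: {len(left)} left vs {len(right)} right "
                    "channels; homologous pairing is positional"
                )

    def regions(self) -> tuple[str, ...]:
        return tuple(self.pairs)

    def channels(self) -> set[str]:
        out: set[str] = set()
        for left, right in self.pairs.values():
            out.update(left)
            out.update(right)
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionMap":
        """Read a plain-text map: ``region <tab> hemisphere <tab> ch1,ch2``."""
        table: dict[str, dict[str, tuple[str, ...]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace("\t", " ").split(None, 2)]
            if len(parts) != 3:
                raise ValueError(f"malformed region-map line: {line!r}")
            region, hemi, chans = parts
            table.setdefault(region.lower(), {})[hemi.lower()] = tuple(
                normalize_label(c) for c in chans.split(",")
            )
        pairs = {}
        for region, hemis in table.items():
            if set(hemis) != {"left", "right"}:
                raise ValueError(f"region {region!r} needs both hemispheres")
            pairs[region] = (hemis["left"], hemis["right"])
        return cls(pairs=pairs, name=Path(path).stem)

    def to_file(self, path: str | Path) -> Path:
        lines = [f"# region map: {self.name}"]
        for region, (left, right) in self.pairs.items():
            lines.append(f"{region}\tleft\t{','.join(left)}")
            lines.append(f"{region}\tright\t{','.join(right)}")
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def default_region_map() -> RegionMap:
    """The study's literal channel grouping (normalised nomenclature).

    Temporal-left is P7 (printed as T5), shared with parietal-left;
    temporal-right is T8 (printed as T4).  Homologous pairs within the
    multi-channel regions follow the standard 10-20 anatomical
    correspondence: (Fp1, Fp2), (F3, F4), (F7, F8); (P3, P4), (P7, P8).
    """
    return RegionMap(
        pairs={
            "frontal": (("Fp1", "F3", "F7"), ("Fp2", "F4", "F8")),
            "central": (("C3",), ("C4",)),
            "temporal": (("P7",), ("T8",)),
            "parietal": (("P3", "P7"), ("P4", "P8")),
            "occipital": (("O1",), ("O2",)),
        },
        name="literal",
    )


def strict_disjoint_region_map() -> RegionMap:
    """Disjoint alternative: temporal = (T7, T8), everything else as default."""
    return RegionMap(
        pairs={
            "frontal": (("Fp1", "F3", "F7"), ("Fp2", "F4", "F8")),
            "central": (("C3",), ("C4",)),
            "temporal": (("T7",), ("T8",)),
            "parietal": (("P3", "P7"), ("P4", "P8")),
            "occipital": (("O1",), ("O2",)),
        },
        name="strict-disjoint",
    )


#: Disjoint anatomical channel -> (region, hemisphere) used by the
#: synthetic-data generator (midline channels carry no hemisphere).
GENERATOR_REGION_OF_CHANNEL: dict[str, tuple[str, str | None]] = {
    "Fp1": ("frontal", "left"), "F3": ("frontal", "left"), "F7": ("frontal", "left"),
    "Fp2": ("frontal", "right"), "F4": ("frontal", "right"), "F8": ("frontal", "right"),
    "Fz": ("frontal", None),
    "C3": ("central", "left"), "C4": ("central", "right"), "Cz": ("central", None),
    "T7": ("temporal", "left"), "T8": ("temporal", "right"),
    "P3": ("parietal", "left"), "P7": ("parietal", "left"),
    "P4": ("parietal", "right"), "P8": ("parietal", "right"),
    "Pz": ("parietal", None),
    "O1": ("occipital", "left"), "O2": ("occipital", "right"),
}


@dataclass(frozen=True)
class RegionalProfile:
    """Region x hemisphere mean HFD plus the whole-brain mean, one subject."""

    hfd: Mapping[str, Mapping[str, float]]  # region -> {"left": .., "right": ..}
    whole_brain: float
    subject_id: str = ""

    def cell(self, region: str, hemisphere: str) -> float:
        return self.hfd[region][hemisphere]


@dataclass(frozen=True)
class HArSProfile:
    """Per-region interhemispheric symmetry indices for one subject."""

    hars: Mapping[str, float]
    subject_id: str = ""


def _lookup(per_channel_hfd: Mapping[str, float]) -> dict[str, float]:
    return {normalize_label(ch): float(v) for ch, v in per_channel_hfd.items()}


def regional_means(
    per_channel_hfd: Mapping[str, float],
    region_map: RegionMap | None = None,
    *,
    whole_brain_channels: str = "all",
    subject_id: str = "",
) -> RegionalProfile:
    """Average per-channel HFD into region x hemisphere cells.

    ``whole_brain_channels='all'`` averages every supplied channel
    (midline included); ``'regional'`` restricts the whole-brain mean to
    channels appearing in the region map.
    """
    region_map = region_map or default_region_map()
    values = _lookup(per_channel_hfd)
    out: dict[str, dict[str, float]] = {}
    for region, (left, right) in region_map.pairs.items():
        cells = {}
        for hemi, chans in (("left", left), ("right", right)):
            missing = [c for c in chans if c not in values]
            if missing:
                raise KeyError(
                    f"region {region!r}/{hemi}: missing channel(s) {missing}"
                )
            cells[hemi] = float(np.mean([values[c] for c in chans]))
        out[region] = cells
    if whole_brain_channels == "all":
        wb = float(np.mean(list(values.values())))
    elif whole_brain_channels == "regional":
        chans = region_map.channels()
        wb = float(np.mean([v for c, v in values.items() if c in chans]))
    else:
        raise ValueError(f"unknown whole_brain_channels {whole_brain_channels!r}")
    return RegionalProfile(hfd=out, whole_brain=wb, subject_id=subject_id)


def hars(left_hfd: float, right_hfd: float) -> float:
    """Interhemispheric symmetry of one homologous pair.

    ``(left - right) / (left + right)``; positive when the left value is
    higher.  Inputs must be positive (HFD is >= 1 by construction).
    """
    if left_hfd <= 0 or right_hfd <= 0:
        raise ValueError(
            f"HArS requires positive inputs, got ({left_hfd}, {right_hfd})"
        )
    return (left_hfd - right_hfd) / (left_hfd + right_hfd)


def regional_hars(
    per_channel_hfd: Mapping[str, float],
    region_map: RegionMap | None = None,
    *,
    subject_id: str = "",
) -> HArSProfile:
    """Per-pair HArS averaged within each region.

    Pairs are the positionally matched (left, right) channels of the
    region map; regions with several pairs report the mean pair index.
    """
    region_map = region_map or default_region_map()
    values = _lookup(per_channel_hfd)
    out: dict[str, float] = {}
    for region, (left, right) in region_map.pairs.items():
        pair_vals = []
        for lch, rch in zip(left, right):
            if lch not in values or rch not in values:
                raise KeyError(f"region {region!r}: missing pair ({lch}, {rch})")
            pair_vals.append(hars(values[lch], values[rch]))
        out[region] = float(np.mean(pair_vals))
    return HArSProfile(hars=out, subject_id=subject_id)
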
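"""Scalp montage: the 24-channel layout and its five-region partition."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

#: The 24 analysis channels, grouped by scalp region.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "AF3", "AF4", "F7", "Fz", "F8", "FC5", "FC6"),
    "temporal": ("FT7", "FT8"),
    "central": ("C3", "Cz", "C4", "CP3", "CP4"),
    "parietal": ("P3", "Pz", "P4", "PO3", "PO4"),
    "occipital": ("O1", "Oz", "O2"),
}

DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    ch for chans in DEFAULT_REGIONS.values() for ch in chans
)

REGION_NAMES: tuple[str, ...] = tuple(DEFAULT_REGIONS)


@dataclass(frozen=True)
class Montage:
    """Mapping from channel label to scalp region, with optional coordinates.

    Parameters
    ----------
    region_of
        Channel label -> region name. Regions must partition the labels.
    coords
        Optional channel label -> (x, y[, z]) plotting coordinates.
    """

    region_of: dict[str, str]
    coords: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for r in self.region_of.values()} - set(REGION_NAMES)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.region_of)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.region_of.values()))

    def channels_in(self, region: str) -> tuple[str, ...]:
        return tuple(c for c, r in self.region_of.items() if r == region)

    def region_index(self, channel_labels: list[str] | tuple[str, ...]):
        """Integer region id per channel, in ``channel_labels`` order."""
        regs = list(self.regions)
        try:
            return [regs.index(self.region_of[c]) for c in channel_labels]
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"channel {exc} not in montage") from exc


def default_montage() -> Montage:
    """The built-in 24-channel five-region montage."""
    region_of = {ch: reg for reg, chans in DEFAULT_REGIONS.items() for ch in chans}
    return Montage(region_of=region_of)


def load_montage(path: str | Path) -> Montage:
    """Read a montage from JSON (``{label: region}`` or ``{label: {region, x, y}}``)
    or CSV with columns ``label, region[, x, y[, z]]``."""
    path = Path(path)
    region_of: dict[str, str] = {}
    coords: dict[str, tuple[float, ...]] = {}
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        for label, val in obj.items():
            if isinstance(val, str):
                region_of[label] = val
            else:
                region_of[label] = val["region"]
                if "x" in val:
                    xyz = [float(val["x"]), float(val["y"])]
                    if "z" in val:
                        xyz.append(float(val["z"]))
                    coords[label] = tuple(xyz)
    else:
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "label":
                    continue
                label, region = row[0].strip(), row[1].strip()
                region_of[label] = region
                if len(row) > 2:
                    coords[label] = tuple(float(v) for v in row[2:] if v.strip())
    return Montage(region_of=region_of, coords=coords)


def save_montage(montage: Montage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(montage.region_of, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "region"])
            for label, region in montage.region_of.items():
                w.writerow([label, region])
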
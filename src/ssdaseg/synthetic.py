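"""Two-domain 3D abdominal phantoms.

The training problem this package addresses needs data with a specific
statistical structure: two imaging "modalities" whose per-organ intensity
distributions disagree (domain shift), per-patient variation in organ
scale, four foreground organs on a background, anisotropic voxel spacing,
and a three-way split of the training pool into labeled source (SL),
small labeled target (TL) and unlabeled target (TU) subsets.  This module
generates exactly that — axis-aligned ellipsoid "organs" at anatomically
inspired anchor positions with jittered centres and per-case scale draws,
painted with domain-specific class intensities plus voxel noise — so the
whole method is exercisable end to end without any external dataset.

Nothing here attempts realistic anatomy or imaging physics; see the
methods note for what these phantoms do and do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LabelMap, Volume, save_label, save_volume

__all__ = ["PhantomSpec", "DomainSample", "SplitDataset", "PlacementError",
           "generate_phantom", "generate_dataset", "write_dataset", "mix_seed",
           "ORGAN_NAMES"]

ORGAN_NAMES = ("background", "liver", "right_kidney", "left_kidney", "spleen")

# anchor centre and scale-range per organ, as fractions of the grid axes;
# anchors are spread so jittered ellipsoids stay pairwise disjoint
_DEFAULT_ANCHORS = {
    1: ((0.34, 0.30, 0.50), (0.16, 0.24)),   # liver: large
    2: ((0.72, 0.28, 0.42), (0.07, 0.11)),   # right kidney: small
    3: ((0.72, 0.72, 0.42), (0.07, 0.11)),   # left kidney: small
    4: ((0.30, 0.74, 0.54), (0.09, 0.14)),   # spleen: intermediate
}

# per-domain per-class (mean, sd) of the case-level intensity draw; the two
# domains invert organ/background contrast, emulating the CT vs T2-SPIR
# mismatch the method has to bridge
_DEFAULT_INTENSITY = {
    "source": {0: (0.30, 0.02), 1: (0.80, 0.03), 2: (0.55, 0.03),
               3: (0.62, 0.03), 4: (0.72, 0.03)},
    "target": {0: (0.65, 0.02), 1: (0.25, 0.03), 2: (0.78, 0.03),
               3: (0.85, 0.03), 4: (0.38, 0.03)},
}


class PlacementError(RuntimeError):
    """An organ could not be placed as a non-empty, disjoint ellipsoid."""


@dataclass
class PhantomSpec:
    """Generative parameters of the phantom family.

    ``organ_scale_ranges`` maps class id to a (lo, hi) interval of fractional
    radii: the ellipsoid semi-axis along grid axis ``i`` is the drawn fraction
    times ``grid_size[i]``.  ``domain_intensity_maps`` maps domain tag to
    {class: (mean, sd)} of the *case-level* intensity draw; ``noise_sd`` is
    the additional i.i.d. voxel noise.
    """
    grid_size: tuple[int, int, int] = (32, 32, 16)
    n_organs: int = 4
    organ_scale_ranges: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {k: v[1] for k, v in _DEFAULT_ANCHORS.items()})
    organ_centers: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {k: v[0] for k, v in _DEFAULT_ANCHORS.items()})
    center_jitter: float = 0.03
    domain_intensity_maps: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=lambda: {d: dict(m) for d, m in _DEFAULT_INTENSITY.items()})
    noise_sd: float = 0.03
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 5.0)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_size):
            raise ValueError(f"grid dims must all be >= 8, got {self.grid_size}")
        if any(n % 2 for n in self.grid_size):
            raise ValueError("grid dims must be divisible by the patch edge (2)")
        if self.n_organs < 1:
            raise ValueError("need at least one organ")
        for c in range(1, self.n_organs + 1):
            if c not in self.organ_scale_ranges or c not in self.organ_centers:
                raise ValueError(f"missing geometry for organ class {c}")
            lo, hi = self.organ_scale_ranges[c]
            if not (0 < lo <= hi):
                raise ValueError(f"bad scale range for class {c}: {(lo, hi)}")
        domains = list(self.domain_intensity_maps)
        if len(domains) >= 2:
            a, b = (self.domain_intensity_maps[d] for d in domains[:2])
            if all(math.isclose(a[c][0], b[c][0]) for c in a):
                raise ValueError(
                    "domain intensity maps are identical for every class; "
                    "there is no domain shift to adapt to")


@dataclass
class DomainSample:
    """One case: a volume, its (optional) label map, and bookkeeping tags."""
    volume: Volume
    label: LabelMap | None
    domain: str
    subset: str          # SL | TL | TU | test
    case_id: str

    @property
    def labeled(self) -> bool:
        return self.label is not None


@dataclass
class SplitDataset:
    SL: list[DomainSample]
    TL: list[DomainSample]
    TU: list[DomainSample]
    test: list[DomainSample]
    labeled_ratio: float
    spec: PhantomSpec | None = None

    def check_invariants(self) -> None:
        target_ids = [s.case_id for s in self.TL + self.TU + self.test]
        if len(set(target_ids)) != len(target_ids):
            raise AssertionError("TL/TU/test overlap in case ids")
        n_train = len(self.TL) + len(self.TU)
        if n_train:
            got = len(self.TL) / n_train
            if abs(got - self.labeled_ratio) > 0.5 / n_train + 1e-9:
                raise AssertionError(
                    f"labeled fraction {got:.3f} != ratio {self.labeled_ratio}")


def mix_seed(seed: int, index: int) -> int:
    """Derive a per-case seed from (dataset seed, case index), splitmix64-style."""
    z = (seed * 0x9E3779B97F4A7C15 + (index + 1) * 0xBF58476D1CE4E5B9) % 2 ** 64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) % 2 ** 64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) % 2 ** 64
    return int((z ^ (z >> 31)) % 2 ** 31)


def _ellipsoid_mask(grid: tuple[int, int, int], center_frac, semi_frac) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in grid]
    dist = np.zeros(grid, dtype=np.float64)
    for i, ax in enumerate(axes):
        c = center_frac[i] * grid[i]
        a = max(semi_frac[i] * grid[i], 1e-9)
        sl = [None, None, None]
        sl[i] = slice(None)
        dist = dist + (((ax - c) / a) ** 2)[tuple(sl)]
    return dist <= 1.0


def generate_phantom(spec: PhantomSpec, domain: str,
                     case_seed: int) -> tuple[Volume, LabelMap]:
    """Generate one case for ``domain``, deterministic in (spec, domain, case_seed).

    Geometry (scales, jittered centres) is drawn first from the case stream,
    so two domains given the same case seed share a label map; intensity and
    voxel noise are drawn afterwards and differ per domain through the
    domain's intensity table.
    """
    spec.validate()
    if domain not in spec.domain_intensity_maps:
        raise ValueError(f"unknown domain {domain!r}; spec knows "
                         f"{tuple(spec.domain_intensity_maps)}")
    rng = np.random.default_rng((spec.seed, case_seed))
    grid = spec.grid_size
    labels = np.zeros(grid, dtype=np.int16)
    for c in range(1, spec.n_organs + 1):
        lo, hi = spec.organ_scale_ranges[c]
        base_center = np.asarray(spec.organ_centers[c])
        placed = False
        for _attempt in range(8):
            scale = rng.uniform(lo, hi)
            center = base_center + rng.uniform(-spec.center_jitter,
                                               spec.center_jitter, size=3)
            mask = _ellipsoid_mask(grid, center, (scale,) * 3)
            if not mask.any():
                raise PlacementError(
                    f"organ class {c} is empty on grid {grid}: radius fraction "
                    f"{scale:.3f} spans less than one voxel — enlarge the grid "
                    "or the scale range")
            if not (mask & (labels > 0)).any():
                labels[mask] = c
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"organ class {c} overlaps previously placed organs on grid "
                f"{grid} after 8 jitter attempts — grid too small for the "
                "configured scale ranges")
    imap = spec.domain_intensity_maps[domain]
    class_values = np.zeros(spec.n_organs + 1, dtype=np.float64)
    for c in range(spec.n_organs + 1):
        mean, sd = imap[c]
        class_values[c] = rng.normal(mean, sd) if sd > 0 else mean
    vol = class_values[labels]
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=grid)
    vmin, vmax = vol.min(), vol.max()
    if vmax > vmin:
        vol = (vol - vmin) / (vmax - vmin)
    else:
        vol = np.zeros_like(vol)
    modality = "synthetic-A" if domain == "source" else "synthetic-B"
    volume = Volume(vol.astype(np.float32), spec.spacing_mm, modality)
    return volume, LabelMap(labels, ORGAN_NAMES[: spec.n_organs + 1])


def generate_dataset(spec: PhantomSpec, n_source: int, n_target: int,
                     labeled_ratio: float, seed: int,
                     n_test: int = 4) -> SplitDataset:
    """Generate SL/TL/TU/test splits of fresh phantom cases.

    ``n_target`` counts *training* target cases; ``n_test`` additional labeled
    target cases form the held-out test set.  TL gets
    ``round(labeled_ratio * n_target)`` cases; the rest are stripped of their
    labels and become TU.
    """
    spec.validate()
    if not (0 < labeled_ratio <= 1):
        raise ValueError(f"labeled_ratio must be in (0, 1], got {labeled_ratio}")
    if n_source < 1 or n_target < 1:
        raise ValueError("need at least one source and one target case")
    n_tl = int(math.floor(labeled_ratio * n_target + 0.5))
    if n_tl == 0:
        raise ValueError(
            f"labeled_ratio={labeled_ratio} yields zero TL cases for "
            f"n_target={n_target}; need n_target >= "
            f"{math.ceil(0.5 / labeled_ratio)}")
    rng = np.random.default_rng(seed)

    def make(domain: str, index: int, subset: str, keep_label: bool) -> DomainSample:
        vol, lab = generate_phantom(spec, domain, mix_seed(seed, index))
        return DomainSample(vol, lab if keep_label else None, domain, subset,
                            case_id=f"{domain[0]}{index:03d}")

    sl = [make("source", i, "SL", True) for i in range(n_source)]
    order = rng.permutation(n_target)
    tl = [make("target", 10_000 + int(i), "TL", True) for i in order[:n_tl]]
    tu = [make("target", 10_000 + int(i), "TU", False) for i in order[n_tl:]]
    test = [make("target", 20_000 + i, "test", True) for i in range(n_test)]
    ds = SplitDataset(SL=sl, TL=tl, TU=tu, test=test,
                      labeled_ratio=labeled_ratio, spec=replace(spec))
    ds.check_invariants()
    return ds


def write_dataset(ds: SplitDataset, outdir: str | Path) -> Path:
    """Write every case as a NIfTI image/label pair plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in ds.SL + ds.TL + ds.TU + ds.test:
        img_path = outdir / f"{sample.case_id}_img.nii.gz"
        save_volume(sample.volume, img_path)
        lab_path = ""
        if sample.label is not None:
            lab_path = str(outdir / f"{sample.case_id}_lab.nii.gz")
            save_label(sample.label, sample.volume.spacing_mm, lab_path)
        rows.append({"case_id": sample.case_id, "domain": sample.domain,
                     "subset": sample.subset, "image": str(img_path),
                     "label": lab_path, "modality": sample.volume.modality})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
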
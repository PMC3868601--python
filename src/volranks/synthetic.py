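"""Synthetic subject cohorts with the variance structure the analysis probes.

The raw study data are segmentation volumes from T1-weighted MR images
in the ADNI and OASIS databanks, which cannot be redistributed. What the
downstream models actually consume, however, is only the per-age-band
distribution of normalized brain volume, and the reported per-band
summary statistics fully parameterize a Gaussian emulation of it:

* normal-like arm — per-band means drifting down with age while the SD
  *increases* (diverging percentile ranks);
* AD-like arm — lower means, SD *decreasing* with age (converging
  ranks).

Default parameters are the reported (n, mean, SD) per band: 227 subjects
in the normal arm, 219 in the AD arm. A ``scale`` factor multiplies the
band sizes for large-sample recovery experiments without touching the
distributional parameters.

Each drawn normalized volume v is expanded into a raw (GM, WM, CSF)
triple — tissue split 60/40 into GM/WM, TIV drawn around 1.4×10⁶
voxel-equivalents — chosen so that (GM+WM)/(GM+WM+CSF) reproduces v to
float precision. These raw volumes exist only to exercise the input
path; they cancel in normalization.

The optional "skewed" family adds a light exponential lower tail to a
15% mixture component, emulating the negatively skewed residuals real
cohorts show at some ages; the Gaussian family is the minimal model
consistent with the reported summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .cohort_io import GroupedCohort, SubjectRecord, group_cohort

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "default_normal_spec",
    "default_ad_spec",
    "generate_cohort",
    "generate_grouped",
    "draw_grouped",
    "spec_to_yaml",
    "spec_from_yaml",
]

AGE_BOUNDS: Dict[int, Tuple[float, float]] = {
    2: (70.0, 75.0),
    3: (75.0, 80.0),
    4: (80.0, 85.0),
    5: (85.0, 90.0),
}

GM_FRACTION = 0.6  # GM share of tissue; cancels in normalization
TIV_MEAN = 1.4e6
TIV_SD = 7.0e4
SKEW_MIX_WEIGHT = 0.15
SKEW_TAIL_SCALE = 1.5  # exponential tail scale, in units of the band SD


@dataclass(frozen=True)
class GroupSpec:
    """Per-band generator parameters: size, mean and SD of normalized volume."""

    code: int
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.code not in (1, 2, 3, 4, 5):
            raise ValueError(f"age-group code must be 1..5, got {self.code}")
        if self.n <= 0:
            raise ValueError(f"group {self.code}: n must be positive")
        if self.sd < 0:
            raise ValueError(f"group {self.code}: sd must be nonnegative")
        if not (0.0 < self.mean - 5 * self.sd and self.mean + 5 * self.sd < 1.0):
            raise ValueError(
                f"group {self.code}: mean ± 5·sd must stay inside (0, 1) to keep "
                "normalized volumes physical"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Full generator configuration: five band specs, seed and family."""

    label: str
    groups: Tuple[GroupSpec, ...]
    seed: int
    family: str = "gaussian"
    band1_age_min: float = 60.0

    def __post_init__(self):
        codes = sorted(g.code for g in self.groups)
        if codes != [1, 2, 3, 4, 5]:
            raise ValueError(f"need exactly one spec per code 1..5, got codes {codes}")
        if self.family not in ("gaussian", "skewed"):
            raise ValueError(f"family must be 'gaussian' or 'skewed', got {self.family!r}")
        if not 55.0 <= self.band1_age_min < 70.0:
            raise ValueError("band-1 minimum age must lie in [55, 70)")

    def group(self, code: int) -> GroupSpec:
        return next(g for g in self.groups if g.code == code)

    @property
    def n(self) -> int:
        return sum(g.n for g in self.groups)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def default_normal_spec(seed: int = 227) -> CohortSpec:
    """Normal-ageing arm defaults: 227 subjects, SD increasing with age."""
    return CohortSpec(
        label="normal",
        groups=(
            GroupSpec(1, 25, 0.7555, 0.0130),
            GroupSpec(2, 89, 0.7569, 0.0196),
            GroupSpec(3, 56, 0.749, 0.0204),
            GroupSpec(4, 34, 0.7418, 0.0193),
            GroupSpec(5, 23, 0.73592, 0.0210),
        ),
        seed=seed,
        band1_age_min=60.0,
    )


def default_ad_spec(seed: int = 219) -> CohortSpec:
    """AD arm defaults: 219 subjects, SD decreasing with age."""
    return CohortSpec(
        label="AD",
        groups=(
            GroupSpec(1, 43, 0.7399, 0.0236),
            GroupSpec(2, 56, 0.7350, 0.0208),
            GroupSpec(3, 49, 0.7330, 0.0209),
            GroupSpec(4, 49, 0.7292, 0.0199),
            GroupSpec(5, 22, 0.71285, 0.0187),
        ),
        seed=seed,
        band1_age_min=55.0,
    )


def _draw_normalized(rng: np.random.Generator, spec: GroupSpec, m: int, family: str) -> np.ndarray:
    v = rng.normal(spec.mean, spec.sd, size=m) if spec.sd > 0 else np.full(m, spec.mean)
    if family == "skewed" and spec.sd > 0:
        mask = rng.random(m) < SKEW_MIX_WEIGHT
        v[mask] -= rng.exponential(SKEW_TAIL_SCALE * spec.sd, size=int(mask.sum()))
    # Physical bound; with mean ± 5·sd inside (0,1) clipping is rare and
    # only the skewed family's tail can reach it.
    return np.clip(v, 1e-6, 1.0 - 1e-6)


def generate_cohort(spec: CohortSpec, scale: float = 1.0) -> List[SubjectRecord]:
    """Draw a full subject table from a cohort spec.

    ``scale`` multiplies every band size (rounded up). Deterministic
    given ``spec.seed``: the same spec yields the identical table.
    """
    if not (scale > 0 and math.isfinite(scale)):
        raise ValueError(f"scale must be a positive finite number, got {scale!r}")
    rng = np.random.default_rng(spec.seed)
    diagnosis = spec.label if spec.label in ("normal", "AD") else "normal"
    records: List[SubjectRecord] = []
    for group in sorted(spec.groups, key=lambda g: g.code):
        m = int(math.ceil(scale * group.n))
        v = _draw_normalized(rng, group, m, spec.family)
        lo, hi = AGE_BOUNDS.get(group.code, (spec.band1_age_min, 70.0))
        ages = rng.uniform(lo, hi, size=m)
        tiv = np.clip(rng.normal(TIV_MEAN, TIV_SD, size=m), 8.0e5, None)
        sexes = rng.choice(["M", "F"], size=m)
        tissue = v * tiv
        for i in range(m):
            records.append(
                SubjectRecord(
                    subject_id=f"{spec.label}-g{group.code}-{i:05d}",
                    age_years=float(ages[i]),
                    sex=str(sexes[i]),
                    diagnosis=diagnosis,
                    gm_volume=float(GM_FRACTION * tissue[i]),
                    wm_volume=float((1.0 - GM_FRACTION) * tissue[i]),
                    csf_volume=float(tiv[i] - tissue[i]),
                )
            )
    return records


def generate_grouped(spec: CohortSpec, scale: float = 1.0) -> GroupedCohort:
    """Generate and immediately band/normalize (convenience for fitting)."""
    return group_cohort(generate_cohort(spec, scale=scale), label=spec.label)


def draw_grouped(spec: CohortSpec, scale: float = 1.0) -> GroupedCohort:
    """Draw normalized volumes straight into banded form.

    Skips synthesizing raw (GM, WM, CSF) records — the fitting stages
    only see normalized values, so this is the path for large-scale
    replicate simulations. Deterministic given ``spec.seed`` (its draw
    sequence differs from :func:`generate_cohort`, which also consumes
    draws for ages, TIV and sex).
    """
    if not (scale > 0 and math.isfinite(scale)):
        raise ValueError(f"scale must be a positive finite number, got {scale!r}")
    rng = np.random.default_rng(spec.seed)
    groups = {}
    for group in sorted(spec.groups, key=lambda g: g.code):
        m = int(math.ceil(scale * group.n))
        groups[group.code] = _draw_normalized(rng, group, m, spec.family)
    return GroupedCohort(label=spec.label, groups=groups)


# ---------------------------------------------------------------------------
# Plain-config round trip


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "label": spec.label,
        "seed": spec.seed,
        "family": spec.family,
        "band1_age_min": spec.band1_age_min,
        "groups": [
            {"code": g.code, "n": g.n, "mean": g.mean, "sd": g.sd}
            for g in sorted(spec.groups, key=lambda g: g.code)
        ],
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def spec_from_yaml(path: str | Path) -> CohortSpec:
    payload = yaml.safe_load(Path(path).read_text())
    return CohortSpec(
        label=payload["label"],
        groups=tuple(
            GroupSpec(code=g["code"], n=g["n"], mean=g["mean"], sd=g["sd"])
            for g in payload["groups"]
        ),
        seed=int(payload.get("seed", 0)),
        family=payload.get("family", "gaussian"),
        band1_age_min=float(payload.get("band1_age_min", 60.0)),
    )
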
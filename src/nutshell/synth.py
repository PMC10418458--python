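"""Synthetic FT-NIR data: mixture design and spectrum simulation.

The real study material (ground nutmeg adulterated with ground nutmeg
shell) is emulated by two endmember spectral populations built from
Gaussian absorption bands at the known lipid- and carbohydrate-associated
NIR wavenumbers, a gravimetric mixture design, and a per-measurement
scatter/noise model:

* nutmeg spectra are relatively homogeneous, shell spectra more variable
  (log-normal per-sample multipliers on band amplitudes);
* a mixture with shell mass fraction ``f`` has the noise-free spectrum
  ``(1 - f) * nutmeg_sample + f * shell_sample`` — a convex combination of
  the *specific* constituent samples, not of population means;
* each of the 5 technical replicates per sample/mixture is distorted as
  ``y = b * x + a + eps`` with a log-normal multiplicative gain ``b``, an
  additive offset ``a`` and i.i.d. channel noise ``eps`` — exactly the
  distortion family that multiplicative scatter correction removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, InfeasibleDesignError, ValidationError
from .grid import DEFAULT_GRID, WavenumberGrid

__all__ = [
    "Band",
    "EndmemberModel",
    "ScatterParams",
    "MixtureSpec",
    "DesignTable",
    "generate_design",
    "validate_design",
    "simulate_endmember_sample",
    "simulate_measurement",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center and width in cm^-1, amplitude
    in absorbance units."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValidationError(
                f"band amplitude must be >= 0, got {self.amplitude}"
            )


@dataclass(frozen=True)
class EndmemberModel:
    """Spectral population model for one pure constituent.

    Parameters
    ----------
    role : str
        ``"nutmeg"`` or ``"shell"``.
    bands : tuple of Band
        Absorption bands; amplitudes are population means.
    baseline_offset, baseline_slope : float
        Non-negative affine baseline; the slope term grows linearly from 0
        at the high-wavenumber end to ``baseline_slope`` at the low end.
    population_sd : float
        SD of the per-sample log-normal multiplier applied independently to
        each band amplitude. Zero means every sample of this population is
        identical.
    """

    role: str
    bands: tuple[Band, ...]
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    population_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("nutmeg", "shell"):
            raise ValidationError(f"unknown endmember role {self.role!r}")
        if self.baseline_offset < 0 or self.baseline_slope < 0:
            raise ValidationError("baseline terms must be non-negative")
        if self.population_sd < 0:
            raise ValidationError("population_sd must be >= 0")

    def mean_spectrum(self, grid: WavenumberGrid) -> np.ndarray:
        """Noise-free population-mean spectrum on ``grid``."""
        return _band_spectrum(self, grid, np.ones(len(self.bands)))


@dataclass(frozen=True)
class ScatterParams:
    """Per-replicate measurement distortion: y = b*x + a + eps.

    sigma_b is the SD of log(b); sigma_a and sigma_eps are absorbance SDs.
    """

    sigma_b: float = 0.0
    sigma_a: float = 0.0
    sigma_eps: float = 0.0
    replicates: int = 5

    def __post_init__(self) -> None:
        if min(self.sigma_b, self.sigma_a, self.sigma_eps) < 0:
            raise ValidationError("scatter SDs must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


@dataclass(frozen=True)
class MixtureSpec:
    """One gravimetric mixture: shell mass fraction f of a specific
    nutmeg/shell sample pair."""

    mixture_id: str
    nutmeg_id: str
    shell_id: str
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"shell fraction must be in [0, 1], got {self.f}")


@dataclass
class DesignTable:
    """Pure samples plus mixtures, with the constraints they were built under."""

    nutmeg_ids: list[str]
    shell_ids: list[str]
    mixtures: list[MixtureSpec]
    forced_levels: tuple[float, ...]
    min_per_nutmeg: int
    min_per_shell: int
    count_range: tuple[int, int] = (15, 23)

    @property
    def n_mixtures(self) -> int:
        return len(self.mixtures)

    def sample_table(self) -> pd.DataFrame:
        """Sample registry: one row per pure sample and per mixture."""
        rows = [
            {"sample_id": nid, "role": "nutmeg", "shell_fraction": 0.0,
             "nutmeg_id": nid, "shell_id": ""}
            for nid in self.nutmeg_ids
        ]
        rows += [
            {"sample_id": sid, "role": "shell", "shell_fraction": 1.0,
             "nutmeg_id": "", "shell_id": sid}
            for sid in self.shell_ids
        ]
        rows += [
            {"sample_id": m.mixture_id, "role": "mixture", "shell_fraction": m.f,
             "nutmeg_id": m.nutmeg_id, "shell_id": m.shell_id}
            for m in self.mixtures
        ]
        return pd.DataFrame(rows)


def _balanced_assignment(ids: list[str], n_slots: int,
                         rng: np.random.Generator) -> list[str]:
    """Random assignment of ids to slots with counts differing by <= 1."""
    out: list[str] = []
    while len(out) < n_slots:
        out.extend(rng.permutation(ids).tolist())
    return out[:n_slots]


def generate_design(
    n_nutmeg: int,
    n_shell: int,
    forced_levels: tuple[float, ...] = (3.0, 7.0),
    per_level_counts: dict[float, int] | None = None,
    min_per_nutmeg: int = 7,
    min_per_shell: int = 30,
    count_range: tuple[int, int] = (15, 23),
    seed: int = 0,
) -> DesignTable:
    """Draw the gravimetric mixture design.

    Every nutmeg sample is mixed with shell at each forced level (3% and
    7% by default). Each additional level (1-10% in 1% steps, 10-50% in
    10% steps in the study design) receives ``per_level_counts[level]``
    mixtures, each between ``count_range`` many; nutmeg and shell partners
    are drawn uniformly at random subject to balancing, so the per-sample
    minimum constraints hold whenever they are arithmetically feasible.

    Levels are percentages (3 means 3% shell by mass).

    Raises
    ------
    InfeasibleDesignError
        Naming the violated constraint when the requested counts cannot
        satisfy the per-sample minima or the per-level count range.
    """
    if n_nutmeg < 1 or n_shell < 1:
        raise InfeasibleDesignError("need at least one nutmeg and one shell sample")
    per_level_counts = dict(per_level_counts or {})

    lo, hi = count_range
    for level, count in per_level_counts.items():
        if level in forced_levels:
            raise InfeasibleDesignError(
                f"level {level}% is a forced level; its count is n_nutmeg"
            )
        if not lo <= count <= hi:
            raise InfeasibleDesignError(
                f"per-level count {count} at {level}% outside [{lo}, {hi}]"
            )

    n_forced = n_nutmeg * len(forced_levels)
    n_other = sum(per_level_counts.values())
    n_total = n_forced + n_other

    # Balanced assignment guarantees these floors; check feasibility up front.
    floor_nutmeg = len(forced_levels) + n_other // n_nutmeg
    if floor_nutmeg < min_per_nutmeg:
        raise InfeasibleDesignError(
            f"per-nutmeg minimum unreachable: at most {floor_nutmeg} mixtures "
            f"guaranteed per nutmeg sample < required {min_per_nutmeg}"
        )
    if n_total // n_shell < min_per_shell:
        raise InfeasibleDesignError(
            f"per-shell minimum unreachable: at most {n_total // n_shell} "
            f"mixtures guaranteed per shell sample < required {min_per_shell}"
        )

    rng = np.random.default_rng(seed)
    nutmeg_ids = [f"N{i + 1:02d}" for i in range(n_nutmeg)]
    shell_ids = [f"S{i + 1:02d}" for i in range(n_shell)]

    mixtures: list[MixtureSpec] = []
    # Forced levels: every nutmeg sample, shell partner balanced-random.
    forced_slots = [(nid, level) for nid in nutmeg_ids for level in forced_levels]
    forced_shells = _balanced_assignment(shell_ids, len(forced_slots), rng)
    for (nid, level), sid in zip(forced_slots, forced_shells):
        mixtures.append(MixtureSpec(
            mixture_id=f"M{len(mixtures) + 1:03d}",
            nutmeg_id=nid, shell_id=sid, f=level / 100.0))

    # Remaining levels: balanced-random nutmeg and shell partners.
    other_slots = [level for level in sorted(per_level_counts)
                   for _ in range(per_level_counts[level])]
    other_nutmegs = _balanced_assignment(nutmeg_ids, len(other_slots), rng)
    other_shells = _balanced_assignment(shell_ids, len(other_slots), rng)
    for level, nid, sid in zip(other_slots, other_nutmegs, other_shells):
        mixtures.append(MixtureSpec(
            mixture_id=f"M{len(mixtures) + 1:03d}",
            nutmeg_id=nid, shell_id=sid, f=level / 100.0))

    design = DesignTable(
        nutmeg_ids=nutmeg_ids, shell_ids=shell_ids, mixtures=mixtures,
        forced_levels=tuple(forced_levels), min_per_nutmeg=min_per_nutmeg,
        min_per_shell=min_per_shell, count_range=count_range)
    validate_design(design)
    return design


def validate_design(design: DesignTable) -> None:
    """Independent audit of a DesignTable against its own constraints.

    Raises ValidationError on the first violated constraint.
    """
    nutmeg_set = set(design.nutmeg_ids)
    shell_set = set(design.shell_ids)
    forced = {round(float(v), 6) for v in design.forced_levels}
    per_nutmeg: dict[str, int] = {nid: 0 for nid in design.nutmeg_ids}
    per_shell: dict[str, int] = {sid: 0 for sid in design.shell_ids}
    forced_seen: dict[str, set[float]] = {nid: set() for nid in design.nutmeg_ids}
    per_level: dict[float, int] = {}

    for m in design.mixtures:
        if m.nutmeg_id not in nutmeg_set:
            raise ValidationError(f"mixture {m.mixture_id}: unknown nutmeg "
                                  f"constituent {m.nutmeg_id!r}")
        if m.shell_id not in shell_set:
            raise ValidationError(f"mixture {m.mixture_id}: unknown shell "
                                  f"constituent {m.shell_id!r}")
        level = round(m.f * 100.0, 6)
        per_nutmeg[m.nutmeg_id] += 1
        per_shell[m.shell_id] += 1
        per_level[level] = per_level.get(level, 0) + 1
        if level in forced:
            forced_seen[m.nutmeg_id].add(level)

    for nid in design.nutmeg_ids:
        missing = forced - forced_seen[nid]
        if missing:
            raise ValidationError(
                f"nutmeg sample {nid} lacks forced level(s) {sorted(missing)}")
        if per_nutmeg[nid] < design.min_per_nutmeg:
            raise ValidationError(
                f"nutmeg sample {nid} appears in {per_nutmeg[nid]} mixtures "
                f"< minimum {design.min_per_nutmeg}")
    for sid in design.shell_ids:
        if per_shell[sid] < design.min_per_shell:
            raise ValidationError(
                f"shell sample {sid} appears in {per_shell[sid]} mixtures "
                f"< minimum {design.min_per_shell}")

    lo, hi = design.count_range
    n_forced_per_level = len(design.nutmeg_ids)
    for level, count in per_level.items():
        if level in forced:
            if count != n_forced_per_level:
                raise ValidationError(
                    f"forced level {level}% has {count} mixtures, expected "
                    f"{n_forced_per_level}")
        elif not lo <= count <= hi:
            raise ValidationError(
                f"level {level}% has {count} mixtures outside [{lo}, {hi}]")


def _band_spectrum(model: EndmemberModel, grid: WavenumberGrid,
                   multipliers: np.ndarray) -> np.ndarray:
    nu = grid.values
    # slope ramps from 0 at the high-wavenumber end to baseline_slope at the
    # low end, keeping the baseline non-negative on the whole grid
    y = model.baseline_offset + model.baseline_slope * (
        (grid.start - nu) / (grid.start - grid.stop))
    for band, mult in zip(model.bands, multipliers):
        if not grid.stop <= band.center <= grid.start:
            raise GridError(
                f"band center {band.center} cm^-1 outside grid "
                f"[{grid.stop}, {grid.start}]")
        y = y + band.amplitude * mult * np.exp(
            -0.5 * ((nu - band.center) / band.width) ** 2)
    return y


def simulate_endmember_sample(
    model: EndmemberModel,
    grid: WavenumberGrid = DEFAULT_GRID,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one pure sample's noise-free spectrum from its population model.

    Each band amplitude gets an independent log-normal multiplier
    exp(population_sd * z); population_sd = 0 reproduces the population
    mean exactly regardless of the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    z = rng.standard_normal(len(model.bands))
    multipliers = np.exp(model.population_sd * z)
    return _band_spectrum(model, grid, multipliers)


def simulate_measurement(
    true_spectrum: np.ndarray,
    scatter: ScatterParams,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Replicate measurements of one sample under the scatter model.

    Each replicate r is ``b_r * x + a_r + eps_r`` with
    ``b_r = exp(N(0, sigma_b^2))``, ``a_r ~ N(0, sigma_a^2)`` and channel
    noise ``eps_r ~ N(0, sigma_eps^2)`` i.i.d. per channel — vial repacking
    between scans makes scatter a replicate-level, not sample-level, effect.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = np.asarray(true_spectrum, dtype=float)
    replicates = []
    for _ in range(scatter.replicates):
        b = float(np.exp(scatter.sigma_b * rng.standard_normal()))
        a = float(scatter.sigma_a * rng.standard_normal())
        eps = scatter.sigma_eps * rng.standard_normal(x.size)
        replicates.append(b * x + a + eps)
    return replicates


def simulate_dataset(
    design: DesignTable,
    nutmeg_model: EndmemberModel,
    shell_model: EndmemberModel,
    scatter: ScatterParams,
    grid: WavenumberGrid = DEFAULT_GRID,
    seed: int = 0,
):
    """Simulate the full measurement campaign for a design.

    Returns a :class:`nutshell.io.Dataset`: one spectrum per replicate per
    sample/mixture, with metadata carrying role, shell fraction,
    constituent ids and 1-based replicate index. Deterministic under
    ``seed``.
    """
    from .io import Dataset  # local import to keep io independent of synth

    rng = np.random.default_rng(seed)
    true_spectra: dict[str, np.ndarray] = {}
    for nid in design.nutmeg_ids:
        true_spectra[nid] = simulate_endmember_sample(nutmeg_model, grid, rng)
    for sid in design.shell_ids:
        true_spectra[sid] = simulate_endmember_sample(shell_model, grid, rng)
    for m in design.mixtures:
        if m.nutmeg_id not in true_spectra or m.shell_id not in true_spectra:
            raise ValidationError(
                f"mixture {m.mixture_id}: missing constituent spectrum")
        true_spectra[m.mixture_id] = (
            (1.0 - m.f) * true_spectra[m.nutmeg_id]
            + m.f * true_spectra[m.shell_id])

    samples = design.sample_table()
    rows, values = [], []
    for rec in samples.itertuples(index=False):
        reps = simulate_measurement(true_spectra[rec.sample_id], scatter, rng)
        for k, y in enumerate(reps, start=1):
            rows.append({
                "measurement_id": f"{rec.sample_id}_r{k}",
                "sample_id": rec.sample_id,
                "role": rec.role,
                "shell_fraction": rec.shell_fraction,
                "nutmeg_id": rec.nutmeg_id,
                "shell_id": rec.shell_id,
                "replicate": k,
            })
            values.append(y)

    meta = pd.DataFrame(rows)
    return Dataset(grid=grid, X=np.asarray(values), meta=meta)
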
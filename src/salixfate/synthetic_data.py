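"""Simulated incubation experiments with known kinetic ground truth.

The generator reproduces the design of the in-vitro study: human fecal
suspension (HFS) incubated with willow bark extract at 2 and 10 mg/ml,
vehicle and plain-buffer fecal controls, and an extract-in-buffer control
without microbes, sampled at 0.5, 4 and 24 h in triplicate.

Each feature follows one kinetic archetype:

* SUBSTRATE - first-order microbial decay, ``A exp(-k1 t)``;
* PRODUCT - microbial formation, ``A (1 - exp(-k1 t))``;
* INTERMEDIATE - series formation and further degradation,
  ``A k1/(k2-k1) (exp(-k1 t) - exp(-k2 t))`` (rise then fall);
* STABLE - constant in every channel where it occurs;
* ABIOTIC_UNSTABLE - first-order decay in every channel including the
  microbe-free extract control (chemical instability, not metabolism);
* MATRIX - fecal-background feature, present in all HFS channels
  regardless of extract addition and absent from the extract control.

Microbial (biotic) kinetics run at rate ``k / inhibition_factor_high_conc``
in the 10 mg/ml series: a minimal mechanism for the slower turnover
observed at the high extract concentration.  Observed areas carry
multiplicative lognormal noise, and areas below the limit of detection
are recorded as not detected (distinct from zero).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chem
from .io import TIME_POINTS, Channel, FeatureTable, make_design

__all__ = [
    "ArchetypeKind",
    "KineticArchetype",
    "FeatureSpec",
    "SyntheticTruth",
    "trajectory",
    "intermediate_peak_time",
    "expected_area",
    "simulate_experiment",
    "study_features",
    "demo_features",
]

BIOTIC_KINDS = frozenset({"SUBSTRATE", "PRODUCT", "INTERMEDIATE"})


class ArchetypeKind(str, enum.Enum):
    SUBSTRATE = "SUBSTRATE"
    INTERMEDIATE = "INTERMEDIATE"
    PRODUCT = "PRODUCT"
    STABLE = "STABLE"
    ABIOTIC_UNSTABLE = "ABIOTIC_UNSTABLE"
    MATRIX = "MATRIX"


@dataclass(frozen=True)
class KineticArchetype:
    """Kinetic class of a feature plus its rate parameters.

    ``amplitude`` is the initial (SUBSTRATE-like) or asymptotic
    (PRODUCT-like) peak area in arbitrary area units.  ``k1``/``k2`` are
    first-order rate constants per hour; INTERMEDIATE uses ``k1`` for
    formation and ``k2`` for onward degradation and requires them to
    differ.  ``inhibition_factor_high_conc`` (>= 1) divides biotic rates
    in the high-concentration series.
    """

    kind: ArchetypeKind
    amplitude: float = 1e6
    k1: float | None = None
    k2: float | None = None
    inhibition_factor_high_conc: float = 1.25

    def __post_init__(self) -> None:
        kind = ArchetypeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.inhibition_factor_high_conc < 1:
            raise ValueError("inhibition factor must be >= 1")
        needs_k1 = kind in (
            ArchetypeKind.SUBSTRATE,
            ArchetypeKind.PRODUCT,
            ArchetypeKind.INTERMEDIATE,
            ArchetypeKind.ABIOTIC_UNSTABLE,
        )
        if needs_k1 and (self.k1 is None or self.k1 <= 0):
            raise ValueError(f"{kind.value} requires a positive rate k1")
        if kind is ArchetypeKind.INTERMEDIATE:
            if self.k2 is None or self.k2 <= 0:
                raise ValueError("INTERMEDIATE requires a positive rate k2")
            if self.k2 == self.k1:
                raise ValueError("INTERMEDIATE rates k1 and k2 must differ")


def trajectory(archetype: KineticArchetype, t: float, inhibited: bool = False) -> float:
    """Noise-free expected area of an archetype at time ``t`` (hours).

    This is the trajectory in an active (fecal-suspension) channel; the
    channel logic (controls, matrix) lives in :func:`expected_area`.
    With ``inhibited`` the biotic rates are divided by the archetype's
    high-concentration inhibition factor.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    a = archetype.amplitude
    kind = archetype.kind
    if kind in (ArchetypeKind.STABLE, ArchetypeKind.MATRIX):
        return a
    factor = archetype.inhibition_factor_high_conc if (
        inhibited and kind.value in BIOTIC_KINDS
    ) else 1.0
    k1 = archetype.k1 / factor
    if kind in (ArchetypeKind.SUBSTRATE, ArchetypeKind.ABIOTIC_UNSTABLE):
        return a * math.exp(-k1 * t)
    if kind is ArchetypeKind.PRODUCT:
        return a * (1.0 - math.exp(-k1 * t))
    # INTERMEDIATE: two-step series A -> B -> C, B observed.
    k2 = archetype.k2 / factor
    return a * k1 / (k2 - k1) * (math.exp(-k1 * t) - math.exp(-k2 * t))


def intermediate_peak_time(archetype: KineticArchetype) -> float:
    """Time (h) at which an INTERMEDIATE trajectory peaks: ln(k2/k1)/(k2-k1)."""
    if archetype.kind is not ArchetypeKind.INTERMEDIATE:
        raise ValueError("peak time is defined for INTERMEDIATE archetypes only")
    return math.log(archetype.k2 / archetype.k1) / (archetype.k2 - archetype.k1)


@dataclass(frozen=True)
class FeatureSpec:
    """Ground truth for one simulated feature."""

    feature_id: str
    mz: float
    rt: float
    archetype: KineticArchetype
    present_concs: tuple[float, ...] = (2.0, 10.0)
    compound_peak_id: int | None = None


def expected_area(
    spec: FeatureSpec, channel: Channel, conc: float, t: float, high_conc: float = 10.0
) -> float:
    """Noise-free expected area of a feature in one design cell.

    Extract-derived features are absent from the vehicle and plain-buffer
    fecal channels; matrix features are present in every fecal channel and
    absent from the extract control.  In the microbe-free extract control
    biotic trajectories are flat: substrates and stable constituents stay
    at their amplitude, microbial products and intermediates never form,
    and only ABIOTIC_UNSTABLE features decay there.
    """
    channel = Channel(channel)
    arch = spec.archetype
    kind = arch.kind
    if channel in (Channel.HFS_VEHICLE, Channel.HFS_PBS):
        return arch.amplitude if kind is ArchetypeKind.MATRIX else 0.0
    if channel is Channel.EXTRACT_CONTROL:
        if kind in (ArchetypeKind.SUBSTRATE, ArchetypeKind.STABLE):
            return arch.amplitude
        if kind is ArchetypeKind.ABIOTIC_UNSTABLE:
            return trajectory(arch, t)
        return 0.0  # PRODUCT / INTERMEDIATE need microbes; MATRIX needs feces
    # HFS_WBE
    if kind is ArchetypeKind.MATRIX:
        return arch.amplitude
    if float(conc) not in {float(c) for c in spec.present_concs}:
        return 0.0
    return trajectory(arch, t, inhibited=float(conc) == float(high_conc))


@dataclass
class SyntheticTruth:
    """Per-feature archetypes and parameters: the recovery-test oracle."""

    features: Dict[str, FeatureSpec]
    sigma: float
    lod: float
    seed: int

    def spec(self, feature_id: str) -> FeatureSpec:
        return self.features[feature_id]

    def expected_label(
        self,
        feature_id: str,
        conc: float,
        concentrations: Sequence[float] = (2.0, 10.0),
        up: float = 2.0,
        down: float = 0.5,
        inter: float = 1.25,
        times: Sequence[float] = TIME_POINTS,
    ) -> str:
        """Archetype-implied triage label from the noise-free closed forms.

        Applies the published ratio rules to the exact trajectories with
        the same precedence as the triage stage (matrix, then fast
        metabolization, then insufficient data, then intermediate /
        increasing / decreasing).  In the noiseless limit a ratio counts
        as significant whenever the two group means differ.
        """
        spec = self.features[feature_id]
        high = max(concentrations)
        if spec.archetype.kind is ArchetypeKind.MATRIX:
            return "MATRIX"

        def detected(channel: Channel, c: float, t: float) -> bool:
            return expected_area(spec, channel, c, t, high) >= self.lod

        ec_present = detected(Channel.EXTRACT_CONTROL, high, times[0])
        hfs_any = any(
            detected(Channel.HFS_WBE, c, t) for c in concentrations for t in times
        )
        if ec_present and not hfs_any:
            return "FAST_METABOLIZED"
        areas = {
            t: expected_area(spec, Channel.HFS_WBE, conc, t, high) for t in times
        }
        censored = {t: (a if a >= self.lod else 0.0) for t, a in areas.items()}
        present = {t: areas[t] >= self.lod for t in times}
        if not any(present.values()):
            return "INSUFFICIENT_DATA"
        t0, t4, t24 = times

        def ratio(num: float, den: float) -> float:
            if den > 0:
                return num / den
            return math.inf if num > 0 else math.nan

        r_4_0 = ratio(censored[t4], censored[t0])
        r_24_0 = ratio(censored[t24], censored[t0])
        r_4_24 = ratio(censored[t4], censored[t24])
        if (
            present[t4]
            and r_4_0 > up
            and censored[t4] != censored[t0]
            and r_4_24 > inter
        ):
            return "INTERMEDIATE"
        if present[t24] and r_24_0 > up and censored[t24] != censored[t0]:
            return "INCREASING"
        if present[t0] and r_24_0 < down and censored[t24] != censored[t0]:
            return "DECREASING"
        return "UNCHANGED"

    def expected_abiotic_flag(
        self, feature_id: str, down: float = 0.5, times: Sequence[float] = TIME_POINTS
    ) -> bool:
        """Whether the extract-control crosscheck should flag this feature."""
        spec = self.features[feature_id]
        if spec.archetype.kind is not ArchetypeKind.ABIOTIC_UNSTABLE:
            return False
        a0 = expected_area(spec, Channel.EXTRACT_CONTROL, 10.0, times[0])
        a24 = expected_area(spec, Channel.EXTRACT_CONTROL, 10.0, times[-1])
        return a0 >= self.lod and a24 < down * a0

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "sigma": self.sigma,
            "lod": self.lod,
            "features": [
                {
                    "feature_id": s.feature_id,
                    "mz": s.mz,
                    "rt": s.rt,
                    "kind": s.archetype.kind.value,
                    "amplitude": s.archetype.amplitude,
                    "k1": s.archetype.k1,
                    "k2": s.archetype.k2,
                    "inhibition_factor_high_conc": s.archetype.inhibition_factor_high_conc,
                    "present_concs": list(s.present_concs),
                    "compound_peak_id": s.compound_peak_id,
                }
                for s in self.features.values()
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        data = yaml.safe_load(Path(path).read_text())
        features = {}
        for row in data["features"]:
            spec = FeatureSpec(
                feature_id=row["feature_id"],
                mz=row["mz"],
                rt=row["rt"],
                archetype=KineticArchetype(
                    kind=ArchetypeKind(row["kind"]),
                    amplitude=row["amplitude"],
                    k1=row["k1"],
                    k2=row["k2"],
                    inhibition_factor_high_conc=row["inhibition_factor_high_conc"],
                ),
                present_concs=tuple(row["present_concs"]),
                compound_peak_id=row["compound_peak_id"],
            )
            features[spec.feature_id] = spec
        return cls(features=features, sigma=data["sigma"], lod=data["lod"], seed=data["seed"])


def simulate_experiment(
    feature_specs: Sequence[FeatureSpec],
    noise_sigma: float = 0.2,
    lod: float = 100.0,
    seed: int | None = None,
    concentrations: Sequence[float] = (2.0, 10.0),
    times: Sequence[float] = TIME_POINTS,
    replicates: int = 3,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate one full incubation experiment.

    Every observed area is the channel trajectory times a multiplicative
    ``lognormal(0, noise_sigma)`` deviate; areas below ``lod`` become
    not-detected cells.  The same seed yields a bit-identical table.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if lod < 0:
        raise ValueError("limit of detection must be non-negative")
    if seed is None:
        raise ValueError("simulation requires an explicit seed")
    ids = [s.feature_id for s in feature_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids in the truth configuration")
    design = make_design(concentrations=concentrations, times=times, replicates=replicates)
    high = max(concentrations)
    expected = np.empty((len(feature_specs), len(design)), dtype=float)
    for i, spec in enumerate(feature_specs):
        for j, (_, row) in enumerate(design.iterrows()):
            expected[i, j] = expected_area(
                spec,
                Channel(row["channel"]),
                float(row["wbe_concentration"]),
                float(row["time_h"]),
                high_conc=high,
            )
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        observed = expected * rng.lognormal(0.0, noise_sigma, size=expected.shape)
    else:
        observed = expected.copy()
    observed[observed < lod] = np.nan
    features = pd.DataFrame(
        {"mz": [s.mz for s in feature_specs], "rt": [s.rt for s in feature_specs]},
        index=pd.Index(ids, name="feature_id"),
    )
    areas = pd.DataFrame(observed, index=features.index, columns=design.index)
    table = FeatureTable(features=features, areas=areas, design=design)
    truth = SyntheticTruth(
        features={s.feature_id: s for s in feature_specs},
        sigma=noise_sigma,
        lod=lod,
        seed=seed,
    )
    return table, truth


def _random_mz_rt(rng: np.random.Generator) -> tuple[float, float]:
    return float(rng.uniform(100.0, 900.0)), float(rng.uniform(1.0, 40.0))


def study_features(
    n_substrate: int = 50,
    n_product: int = 50,
    n_intermediate: int = 50,
    n_stable: int = 50,
    n_abiotic: int = 50,
    n_matrix: int = 20,
    n_fast: int = 10,
    seed: int = 0,
    inhibition_factor: float = 1.25,
) -> list[FeatureSpec]:
    """Feature population used for recovery studies.

    Rate constants are drawn from narrow ranges whose closed-form ratios
    clear the triage thresholds with at least a two-fold margin at both
    concentrations: substrates/products/abiotic decays at 0.15-0.4 /h and
    intermediates with formation at 0.155-0.17 /h and degradation 0.04 /h
    faster.  Fast-metabolized features are substrates whose decay (20 /h)
    censors them below the detection limit everywhere in fecal channels
    even at the inhibited high-concentration rate.
    """
    rng = np.random.default_rng(seed)
    specs: list[FeatureSpec] = []

    def add(kind: ArchetypeKind, n: int, make_rates) -> None:
        for _ in range(n):
            mz, rt = _random_mz_rt(rng)
            amplitude = float(rng.uniform(2e5, 2e6))
            k1, k2 = make_rates()
            arch = KineticArchetype(
                kind=kind,
                amplitude=amplitude,
                k1=k1,
                k2=k2,
                inhibition_factor_high_conc=inhibition_factor,
            )
            specs.append(
                FeatureSpec(
                    feature_id=f"F{len(specs) + 1:04d}", mz=mz, rt=rt, archetype=arch
                )
            )

    def decay():
        return float(rng.uniform(0.15, 0.4)), None

    def inter_rates():
        k1 = float(rng.uniform(0.155, 0.17))
        return k1, k1 + 0.04

    add(ArchetypeKind.SUBSTRATE, n_substrate, decay)
    add(ArchetypeKind.PRODUCT, n_product, decay)
    add(ArchetypeKind.INTERMEDIATE, n_intermediate, inter_rates)
    add(ArchetypeKind.STABLE, n_stable, lambda: (None, None))
    add(ArchetypeKind.ABIOTIC_UNSTABLE, n_abiotic, decay)
    add(ArchetypeKind.MATRIX, n_matrix, lambda: (None, None))
    add(ArchetypeKind.SUBSTRATE, n_fast, lambda: (40.0, None))
    return specs


def demo_features(seed: int = 0, inhibition_factor: float = 1.25) -> list[FeatureSpec]:
    """Library-linked demo population covering all fate labels.

    Maps features onto willow-bark compounds so that annotation and the
    pathway overlays are exercised end to end: glycosides and flavan-3-ols
    as substrates, valerolactones and the naringenin aglycone as
    intermediates, ring-fission acids as products (some formed only at
    2 mg/ml, so the 10 mg/ml record is data-starved), the two
    coumaroyl-glucosides as abiotically unstable, plus unannotated matrix
    background features.
    """
    from .annotate import load_library

    rng = np.random.default_rng(seed)
    library = {rec.peak_id: rec for rec in load_library()}
    plan: list[tuple[int, ArchetypeKind, tuple[float, ...]]] = [
        (10, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (47, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (37, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (41, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (19, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (7, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (18, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (44, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (30, ArchetypeKind.SUBSTRATE, (2.0, 10.0)),
        (56, ArchetypeKind.INTERMEDIATE, (2.0, 10.0)),
        (28, ArchetypeKind.INTERMEDIATE, (2.0, 10.0)),
        (13, ArchetypeKind.INTERMEDIATE, (2.0,)),
        (12, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (38, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (14, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (6, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (16, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (17, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (34, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (42, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (54, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (15, ArchetypeKind.PRODUCT, (2.0, 10.0)),
        (20, ArchetypeKind.PRODUCT, (2.0,)),
        (35, ArchetypeKind.PRODUCT, (2.0,)),
        (49, ArchetypeKind.PRODUCT, (2.0,)),
        (8, ArchetypeKind.STABLE, (2.0, 10.0)),
        (51, ArchetypeKind.ABIOTIC_UNSTABLE, (2.0, 10.0)),
        (53, ArchetypeKind.ABIOTIC_UNSTABLE, (2.0, 10.0)),
    ]
    fast_peaks = [26, 31, 57]
    specs: list[FeatureSpec] = []

    def rates_for(kind: ArchetypeKind) -> tuple[float | None, float | None]:
        if kind is ArchetypeKind.INTERMEDIATE:
            k1 = float(rng.uniform(0.155, 0.17))
            return k1, k1 + 0.04
        if kind in (ArchetypeKind.SUBSTRATE, ArchetypeKind.PRODUCT, ArchetypeKind.ABIOTIC_UNSTABLE):
            return float(rng.uniform(0.15, 0.4)), None
        return None, None

    for peak_id, kind, concs in plan:
        rec = library[peak_id]
        k1, k2 = rates_for(kind)
        specs.append(
            FeatureSpec(
                feature_id=f"F{len(specs) + 1:04d}",
                mz=chem.mz_from_neutral(rec.theoretical_mass),
                rt=rec.rt,
                archetype=KineticArchetype(
                    kind=kind,
                    amplitude=float(rng.uniform(2e5, 2e6)),
                    k1=k1,
                    k2=k2,
                    inhibition_factor_high_conc=inhibition_factor,
                ),
                present_concs=concs,
                compound_peak_id=peak_id,
            )
        )
    for peak_id in fast_peaks:
        rec = library[peak_id]
        specs.append(
            FeatureSpec(
                feature_id=f"F{len(specs) + 1:04d}",
                mz=chem.mz_from_neutral(
                    rec.theoretical_mass if rec.curation_note is None else rec.printed_mass
                ),
                rt=rec.rt,
                archetype=KineticArchetype(
                    kind=ArchetypeKind.SUBSTRATE,
                    amplitude=float(rng.uniform(2e5, 2e6)),
                    k1=40.0,
                    inhibition_factor_high_conc=inhibition_factor,
                ),
                present_concs=(2.0, 10.0),
                compound_peak_id=peak_id,
            )
        )
    for _ in range(5):
        mz, rt = _random_mz_rt(rng)
        specs.append(
            FeatureSpec(
                feature_id=f"F{len(specs) + 1:04d}",
                mz=mz,
                rt=rt,
                archetype=KineticArchetype(
                    kind=ArchetypeKind.MATRIX, amplitude=float(rng.uniform(2e5, 2e6))
                ),
            )
        )
    return specs
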
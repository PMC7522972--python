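"""Forward simulation of IR-CPMG decay data and synthetic study cohorts.

The measured signal of an inversion-recovery/CPMG experiment over a set of
discrete relaxation reservoirs is

    M(t1_i, t2_j) = sum_k A_k (1 - 2 beta exp(-t1_i/T1_k)) exp(-t2_j/T2_k)

with inversion efficiency ``beta`` (1 for a perfect 180-degree pulse) and
i.i.d. additive Gaussian noise on every (t1, echo) point.  The cohort
generator emulates a multi-subject study by jittering preset reservoir
parameters log-normally per subject, so every subject carries an
individual "molecular fingerprint" of the same phenotype family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (
    AcquisitionScheme,
    PhenotypeModel,
    RelaxationReservoir,
    TailSpec,
    preset_phenotype,
)

__all__ = [
    "DecayData",
    "CohortSpec",
    "CohortManifest",
    "SubjectRecord",
    "simulate_decay",
    "generate_cohort",
    "subject_seed",
    "CLASS_OF_PHENOTYPE",
]

# Study-class semantics: oxidation is the disease model (clinical
# methemoglobinemia), wild type is the healthy control, structural
# hemoglobin variants form their own class.
CLASS_OF_PHENOTYPE = {
    "wild_type": "non_disease",
    "oxygenated": "non_disease",
    "oxidized": "disease",
    "partially_oxidized": "disease",
    "deoxygenated": "disease",
    "hbe": "variant",
    "hbd": "variant",
    "rare_beta_thal": "variant",
}

_SUBTYPE = {"oxidized": "oxidized_hb", "partially_oxidized": "partially_oxidized_hb"}


@dataclass(frozen=True)
class DecayData:
    """2D magnetization matrix over (inversion times x echo times)."""

    signal: np.ndarray  # (n_t1_steps, n_echoes)
    t1_axis_ms: np.ndarray
    t2_axis_ms: np.ndarray
    scheme: AcquisitionScheme
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.shape != (len(self.t1_axis_ms), len(self.t2_axis_ms)):
            raise ValueError(
                f"signal shape {self.signal.shape} does not match axes "
                f"({len(self.t1_axis_ms)}, {len(self.t2_axis_ms)})"
            )


def simulate_decay(
    model: PhenotypeModel,
    scheme: AcquisitionScheme | None = None,
    seed: int | None = None,
    efficiency: float = 1.0,
) -> DecayData:
    """Simulate an IR-CPMG decay matrix for one phenotype.

    Parameters
    ----------
    model
        Phenotype (reservoirs plus optional tail), amplitudes summing to 1.
    scheme
        Acquisition settings; defaults to the standard benchtop protocol
        (echo time 200 us, 4000 echoes, 32 log-spaced t1 steps).
    seed
        Seeds the additive noise; ignored when ``scheme.noise_sd == 0``.
    efficiency
        Inversion efficiency beta in (0, 1]; 1 means a perfect 180 pulse.
    """
    if scheme is None:
        scheme = AcquisitionScheme()
    if not 0 < efficiency <= 1:
        raise ValueError("inversion efficiency must be in (0, 1]")
    t1 = scheme.t1_ladder_ms
    t2 = scheme.echo_times_ms
    signal = np.zeros((scheme.n_t1_steps, scheme.n_echoes))
    for comp in model.components():
        rec = 1.0 - 2.0 * efficiency * np.exp(-t1 / comp.t1_ms)
        dec = np.exp(-t2 / comp.t2_ms)
        signal += comp.amplitude * np.outer(rec, dec)
    if scheme.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, scheme.noise_sd, signal.shape)
    return DecayData(
        signal=signal,
        t1_axis_ms=t1,
        t2_axis_ms=t2,
        scheme=scheme,
        provenance={
            "phenotype": model.state,
            "seed": seed,
            "noise_sd": scheme.noise_sd,
            "efficiency": efficiency,
        },
    )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    phenotype: str
    class_label: str  # disease | non_disease | variant
    subtype: str
    seed: int


@dataclass(frozen=True)
class CohortManifest:
    subjects: tuple[SubjectRecord, ...]
    jitter_sd: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for s in self.subjects:
            expect = CLASS_OF_PHENOTYPE[s.phenotype]
            if s.class_label != expect:
                raise ValueError(
                    f"{s.subject_id}: phenotype {s.phenotype!r} implies "
                    f"class {expect!r}, got {s.class_label!r}"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Composition and variability of a synthetic study cohort.

    The default 32-subject composition mixes healthy wild type, fully and
    partially oxidized disease samples, and three structural variants.
    ``jitter_sd`` is the log-normal sigma applied multiplicatively to every
    reservoir parameter per subject (5% inter-subject variability).
    ``partial_oxidation_range`` bounds the uniform factor scaling the
    oxidized tail amplitude for the partially-oxidized subtype.
    """

    counts: tuple[tuple[str, int], ...] = (
        ("wild_type", 10),
        ("oxidized", 8),
        ("partially_oxidized", 6),
        ("hbe", 3),
        ("hbd", 3),
        ("rare_beta_thal", 2),
    )
    jitter_sd: float = 0.05
    scheme: AcquisitionScheme = AcquisitionScheme(n_echoes=2000)
    partial_oxidation_range: tuple[float, float] = (0.2, 0.8)
    size: int = 32

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.counts)
        if total != self.size:
            raise ValueError(
                f"phenotype counts sum to {total}, expected size {self.size}"
            )
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        lo, hi = self.partial_oxidation_range
        if not 0 < lo <= hi < 1:
            raise ValueError("partial oxidation factors must lie in (0, 1)")


def subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject seed: cohorts are extensible without reshuffling."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(subject_id.encode())) % (2**31)


def _jitter_model(model: PhenotypeModel, sd: float,
                  rng: np.random.Generator) -> PhenotypeModel:
    """Multiplicative log-normal jitter on every reservoir parameter."""
    if sd == 0:
        return model

    def f() -> float:
        return float(np.exp(rng.normal(0.0, sd)))

    reservoirs = tuple(
        replace(r, t1_ms=r.t1_ms * f(), t2_ms=r.t2_ms * f(),
                amplitude=r.amplitude * f())
        for r in model.reservoirs
    )
    tail = model.tail
    if tail is not None:
        tail = TailSpec(
            start=(tail.start[0] * f(), tail.start[1] * f()),
            end=(tail.end[0] * f(), tail.end[1] * f()),
            n_components=tail.n_components,
            total_amplitude=tail.total_amplitude * f(),
        )
    return PhenotypeModel(state=model.state, reservoirs=reservoirs, tail=tail)


def _base_model(phenotype: str, spec: CohortSpec,
                rng: np.random.Generator) -> PhenotypeModel:
    if phenotype == "partially_oxidized":
        model = preset_phenotype("oxidized")
        lo, hi = spec.partial_oxidation_range
        factor = float(rng.uniform(lo, hi))
        tail = replace(model.tail,
                       total_amplitude=model.tail.total_amplitude * factor)
        return PhenotypeModel(state="partially_oxidized",
                              reservoirs=model.reservoirs, tail=tail)
    return preset_phenotype(phenotype)


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int = 0,
) -> tuple[CohortManifest, list[DecayData]]:
    """Generate a reproducible synthetic cohort.

    Every subject draws an individual seed from the global seed and its
    subject id, then jitters its phenotype preset and simulates one decay
    matrix.  Identical (spec, seed) pairs reproduce bit-identical output.
    """
    if spec is None:
        spec = CohortSpec()
    subjects: list[SubjectRecord] = []
    data: list[DecayData] = []
    idx = 0
    for phenotype, n in spec.counts:
        if phenotype not in CLASS_OF_PHENOTYPE:
            raise ValueError(f"unknown phenotype {phenotype!r} in cohort spec")
        for _ in range(n):
            idx += 1
            sid = f"S{idx:03d}"
            s_seed = subject_seed(seed, sid)
            rng = np.random.default_rng(s_seed)
            model = _jitter_model(_base_model(phenotype, spec, rng),
                                  spec.jitter_sd, rng)
            noise_seed = int(rng.integers(0, 2**31))
            decay = simulate_decay(model, spec.scheme, seed=noise_seed)
            decay.provenance.update(subject_id=sid, phenotype=phenotype)
            subjects.append(SubjectRecord(
                subject_id=sid,
                phenotype=phenotype,
                class_label=CLASS_OF_PHENOTYPE[phenotype],
                subtype=_SUBTYPE.get(phenotype, phenotype),
                seed=s_seed,
            ))
            data.append(decay)
    manifest = CohortManifest(
        subjects=tuple(subjects),
        jitter_sd=spec.jitter_sd,
        noise_sd=spec.scheme.noise_sd,
        seed=seed,
    )
    return manifest, data
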
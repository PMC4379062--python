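"""Synthetic serum-handling studies.

Emulates the experimental design of the pre-storage handling study: 19
donors contribute 13 aliquots each (1 immediately frozen reference, 9
handling aliquots = {dry ice, wet ice, room temperature} x {12, 24, 36} h,
3 extra freeze-thaw aliquots with 2-4 total thaws), plus 5 pooled-serum and
3 blank (zero) samples on each of 4 kit plates, with all aliquots of one
donor measured on the same plate.

Concentrations follow a multiplicative (log-normal) model::

    log x = log baseline + plate + donor + treatment(temp, delay)
            + ftc_slope * (thaws - 1) + noise

The donor intercept has a dominant component shared across all metabolites
(a per-sample concentration scale, the reason metabolite *ratios* remove
most inter-individual variation) plus a small metabolite-specific part.
Room-temperature degradation is implanted per metabolite class: the eight
abundant lysophosphatidylcholines rise, and - when coupling is on - their
molar gain is deducted from a pool of diacyl-phosphatidylcholines so the
total choline-lipid mass is conserved in expectation; several amino acids
rise while glutamine drifts slightly down; decadienylcarnitine steps down
within the first 12 h; wet-ice effects are attenuated and begin only after
24 h; dry ice and freeze-thaw cycles are null.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import ConcentrationDataset, SampleAnnotation
from .panel import PanelDefinition, build_p150_panel

TEMP_SHORT = {"dry_ice": "dry", "wet_ice": "wet", "rt": "rt"}


@dataclass(frozen=True)
class DegradationProfile:
    """Treatment response of one metabolite (or one class).

    ``rt_slope`` is the per-hour change of log concentration at room
    temperature for ``kind="linear"``; for ``kind="step"`` it is the total
    log step reached at the first sampled delay (12 h) and held thereafter.
    On wet ice the room-temperature trend is multiplied by
    ``wet_attenuation`` and starts only ``onset_h`` hours into the delay.
    Dry ice is always null.  ``coupling`` marks lysoPC gains that are drawn
    from the diacyl-PC pool.
    """

    target: str  # metabolite id or metabolite class
    rt_slope: float
    wet_attenuation: float = 0.15
    onset_h: float = 24.0
    coupling: bool = False
    kind: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_attenuation <= 1.0:
            raise ValueError("wet_attenuation must lie in [0, 1]")
        if self.kind not in ("linear", "step"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    def log_shift(self, temperature: str, delay_h: float) -> float:
        """Implanted log-concentration shift for one handling condition."""
        if temperature == "dry_ice" or delay_h <= 0:
            return 0.0
        if self.kind == "step":
            if temperature == "rt":
                return self.rt_slope if delay_h >= 12 else 0.0
            if temperature == "wet_ice":
                active = delay_h >= max(12.0, self.onset_h)
                return self.wet_attenuation * self.rt_slope if active else 0.0
            return 0.0
        if temperature == "rt":
            return self.rt_slope * delay_h
        if temperature == "wet_ice":
            return self.wet_attenuation * self.rt_slope * max(0.0, delay_h - self.onset_h)
        return 0.0


#: lysoPC species that rise at room temperature (all abundant species except
#: lysoPC(18:2), which stays flat); per-species hydrolysis rates differ
LYSO_RISER_SLOPES = {
    "lysoPC(16:0)": 0.026, "lysoPC(18:0)": 0.025, "lysoPC(18:1)": 0.023,
    "lysoPC(17:0)": 0.022, "lysoPC(14:0)": 0.019, "lysoPC(16:1)": 0.018,
    "lysoPC(20:4)": 0.015, "lysoPC(20:3)": 0.013,
}
LYSO_RISERS = tuple(LYSO_RISER_SLOPES)

#: diacyl-PC pool from which the lysoPC gain is deducted when coupling is on,
#: with relative susceptibility of each species to hydrolysis
COUPLING_POOL_SUSCEPTIBILITY = {
    "PC(30:0)": 1.3, "PC(32:0)": 1.3, "PC(32:1)": 1.4, "PC(32:2)": 1.2,
    "PC(34:2)": 0.9, "PC(34:3)": 1.1, "PC(34:4)": 1.3, "PC(36:5)": 0.8,
}
COUPLING_POOL = tuple(COUPLING_POOL_SUSCEPTIBILITY)

_AMINO_RT_SLOPES = {
    "Ser": 0.020,
    "Gly": 0.010,
    "Phe": 0.010,
    "Orn": 0.009,
    "Arg": 0.008,
    "xLeu": 0.007,
    # glutamine drifts down, deliberately below single-metabolite
    # significance at 19 donors; it surfaces through ratios
    "Gln": -0.0008,
}


def default_profiles() -> list[DegradationProfile]:
    """Default degradation profiles implanting the study's direction pattern."""
    profiles = [
        DegradationProfile(m, rt_slope=slope, coupling=True)
        for m, slope in LYSO_RISER_SLOPES.items()
    ]
    profiles.append(DegradationProfile("lysoPC(18:2)", rt_slope=0.0))
    profiles.extend(
        DegradationProfile(m, rt_slope=s) for m, s in _AMINO_RT_SLOPES.items()
    )
    # early catabolism of decadienylcarnitine: down within 12 h, then flat;
    # slightly low on wet ice already at 12 h
    profiles.append(
        DegradationProfile(
            "C10:2", rt_slope=-0.40, wet_attenuation=0.4, onset_h=0.0, kind="step"
        )
    )
    # mild ether-PC hydrolysis
    profiles.append(DegradationProfile("PC(O-34:1)", rt_slope=-0.007))
    return profiles


# -- default baselines ------------------------------------------------------

#: explicit baseline serum concentrations (uM) for abundant/key metabolites
_BASELINES = {
    # amino acids
    "Arg": 100.0, "Gln": 580.0, "Gly": 250.0, "His": 80.0, "Met": 25.0,
    "Orn": 60.0, "Phe": 55.0, "Pro": 180.0, "Ser": 94.0, "Thr": 130.0,
    "Trp": 55.0, "Tyr": 60.0, "Val": 230.0, "xLeu": 180.0,
    "H1": 4600.0, "C0": 40.0,
    "C2": 8.0, "C3": 0.4, "C10:2": 0.05,
    # lysophosphatidylcholines
    "lysoPC(14:0)": 3.5, "lysoPC(16:0)": 50.0, "lysoPC(16:1)": 5.0,
    "lysoPC(17:0)": 4.0, "lysoPC(18:0)": 28.0, "lysoPC(18:1)": 25.0,
    "lysoPC(18:2)": 38.0, "lysoPC(20:3)": 3.0, "lysoPC(20:4)": 9.0,
    # abundant diacyl PCs
    "PC(30:0)": 4.0, "PC(32:0)": 15.0, "PC(32:1)": 18.0, "PC(32:2)": 8.0,
    "PC(34:1)": 220.0, "PC(34:2)": 280.0, "PC(34:3)": 45.0, "PC(34:4)": 8.0,
    "PC(36:1)": 60.0, "PC(36:2)": 260.0, "PC(36:3)": 160.0, "PC(36:4)": 210.0,
    "PC(36:5)": 20.0, "PC(36:6)": 8.0, "PC(38:3)": 70.0, "PC(38:4)": 130.0,
    "PC(38:5)": 70.0, "PC(38:6)": 90.0, "PC(40:4)": 4.0, "PC(40:5)": 8.0,
    "PC(40:6)": 30.0,
    # abundant ether PCs
    "PC(O-34:1)": 12.0, "PC(O-34:2)": 13.0, "PC(O-36:2)": 13.0,
    "PC(O-36:3)": 8.0, "PC(O-38:4)": 15.0,
    # sphingomyelins
    "SM(16:0)": 110.0, "SM(16:1)": 17.0, "SM(18:0)": 25.0, "SM(18:1)": 12.0,
    "SM(24:0)": 22.0, "SM(24:1)": 55.0, "SM(OH)(22:1)": 12.0,
    "SM(OH)(22:2)": 10.0,
}

#: log-uniform baseline ranges (uM) used for metabolites without an explicit entry
_CLASS_RANGES = {
    "amino_acid": (20.0, 250.0),
    "hexose": (3000.0, 6000.0),
    "carnitine": (25.0, 50.0),
    "acylcarnitine": (0.02, 0.3),
    "sphingomyelin": (1.0, 15.0),
    "pc_aa": (0.5, 6.0),
    "pc_ae": (0.5, 6.0),
    "lyso_pc": (0.2, 0.5),
}

#: metabolites implanted to fail the detection-limit criterion
QC_FAIL_LOD = (
    "C3:1", "C3-OH", "C3-DC", "C4:1", "C4-OH", "C5:1", "C5:1-DC", "C5-OH",
    "C5-DC", "C5-M-DC", "C6:1", "C7-DC", "C8:1", "C12-DC", "C14:1-OH",
    "C14:2-OH", "C16:2", "C16-OH", "C16:1-OH", "C16:2-OH",
    "lysoPC(6:0)", "lysoPC(24:0)", "lysoPC(26:0)", "lysoPC(26:1)",
    "lysoPC(28:0)", "lysoPC(28:1)",
)

#: metabolites implanted to fail the pool-CV criterion
QC_FAIL_CV = (
    "PC(24:0)", "PC(26:0)", "PC(38:0)", "PC(42:0)",
    "PC(O-30:0)", "PC(O-40:0)", "PC(O-42:0)",
    "PC(O-44:4)", "PC(O-44:5)", "PC(O-44:6)",
)


def default_baselines(panel: PanelDefinition) -> dict[str, float]:
    """Baseline concentration (uM) per panel metabolite.

    Explicit values for key metabolites; the remainder is drawn
    deterministically (hash of the metabolite id) from a class-typical
    log-uniform range, so baselines do not depend on the master seed.
    """
    out: dict[str, float] = {}
    for met in panel.metabolites:
        if met.id in _BASELINES:
            out[met.id] = _BASELINES[met.id]
        else:
            lo, hi = _CLASS_RANGES[met.mclass]
            u = (zlib.crc32(met.id.encode()) % 10_000) / 10_000.0
            out[met.id] = float(lo * (hi / lo) ** u)
    return out


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator.

    Defaults are the study conditions: 19 donors on 4 plates, the full
    degradation profile set, a shared per-donor concentration scale
    (SD 0.20, log) plus small metabolite-specific donor terms that grow
    towards trace species, modest donor-to-donor degradation-rate spread,
    residual SD 0.10 (0.05 for amino acids, whose assay precision is
    higher) growing towards trace species in subject aliquots, and 36
    implanted quality-control failures so that a default run retains 127
    of 163 metabolites.
    """

    panel: PanelDefinition = field(default_factory=build_p150_panel)
    n_participants: int = 19
    baseline: Optional[dict[str, float]] = None  # uM; default per panel
    sd_between: float = 0.20
    sd_specific: float = 0.06
    sd_specific_by_class: dict[str, float] = field(
        default_factory=lambda: {"amino_acid": 0.06}
    )
    sd_class: float = 0.0
    sp_half_um: float = 5.0
    sp_factor_cap: float = 2.2
    sd_rate: float = 0.06
    sd_rate_aliquot: float = 0.25
    rate_cap: float = 1.2
    sd_noise: float = 0.10
    sd_noise_by_class: dict[str, float] = field(
        default_factory=lambda: {"amino_acid": 0.05}
    )
    noise_half_um: float = 5.0
    noise_factor_cap: float = 2.2
    profiles: Optional[list[DegradationProfile]] = None  # default profiles
    coupling_pool: Sequence[str] = COUPLING_POOL
    coupling_susceptibility: dict[str, float] = field(
        default_factory=lambda: dict(COUPLING_POOL_SUSCEPTIBILITY)
    )
    ftc_slope: dict[str, float] = field(default_factory=dict)
    n_plates: int = 4
    pool_per_plate: int = 5
    zero_per_plate: int = 3
    zero_floor_frac: float = 0.004
    plate_effect_sd: float = 0.0
    qc_fail_lod: Sequence[str] = QC_FAIL_LOD
    qc_fail_cv: Sequence[str] = QC_FAIL_CV
    qc_fail_zero_frac: float = 0.6
    qc_fail_pool_sd: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profiles is None:
            self.profiles = default_profiles()
        if self.baseline is None:
            self.baseline = default_baselines(self.panel)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_plates < 1:
            raise ValueError("need at least one participant and one plate")
        if self.sd_between <= 0 or self.sd_noise <= 0:
            raise ValueError("all SDs must be positive")
        if min(self.sd_specific, self.sd_class, self.sd_rate) < 0:
            raise ValueError("variance components must be nonnegative")
        missing = [m for m in self.panel.ids if m not in self.baseline]
        if missing:
            raise ValueError(f"no baseline for {missing[:5]}...")
        for prof in self.profiles:
            if prof.target not in self.panel and prof.target not in (
                self.panel.class_counts()
            ):
                raise ValueError(f"profile targets unknown metabolite {prof.target!r}")
        # donor variation must dominate the typical displacement of a
        # handling sample (averaged over the 9 conditions), per metabolite
        conds = [(t, d) for t in ("dry_ice", "wet_ice", "rt") for d in (12, 24, 36)]
        rel = []
        for m in self.panel.ids:
            disp = np.mean([abs(self.expected_log_shift(m, t, d)) for t, d in conds])
            if disp > 0:
                donor_sd = np.sqrt(
                    self.sd_between**2 + self.specific_sd(m) ** 2 + self.sd_class**2
                )
                rel.append(disp / donor_sd)
        if rel and np.median(rel) >= 1.0:
            raise ValueError(
                "donor variation must dominate the typical implanted shift"
            )

    # -- derived helpers ----------------------------------------------------
    def noise_sd(self, metabolite_id: str) -> float:
        mclass = self.panel.class_of(metabolite_id)
        return self.sd_noise_by_class.get(mclass, self.sd_noise)

    def subject_noise_sd(self, metabolite_id: str) -> float:
        """Residual SD for individual subject aliquots.

        Assay + matrix variability is worse for trace species in individual
        sera than in the homogeneous pooled material, so the class residual
        SD grows towards low baselines (same half-saturation form as the
        donor-specific SD, with its own cap).  Pool and zero samples use
        the unscaled :meth:`noise_sd`.
        """
        b = self.baseline[metabolite_id] if self.baseline else None
        factor = 1.0
        if b is not None and b > 0:
            factor = min(np.sqrt(1.0 + self.noise_half_um / b), self.noise_factor_cap)
        return self.noise_sd(metabolite_id) * factor

    def specific_sd(self, metabolite_id: str) -> float:
        """Metabolite-specific donor SD (beyond the shared per-donor scale).

        Lipid species carry most of it (lipoprotein-composition
        differences); amino acids are comparatively homeostatic.  The
        relative composition of trace species varies more between donors
        than that of abundant ones, so the SD grows towards low baselines
        (factor ``sqrt(1 + sp_half_um/baseline)``, capped).
        """
        mclass = self.panel.class_of(metabolite_id)
        base_sd = self.sd_specific_by_class.get(mclass, self.sd_specific)
        b = self.baseline[metabolite_id] if self.baseline else None
        if b is None or b <= 0:
            return base_sd
        factor = min(np.sqrt(1.0 + self.sp_half_um / b), self.sp_factor_cap)
        return base_sd * factor

    def profile_for(self, metabolite_id: str) -> Optional[DegradationProfile]:
        for prof in self.profiles:
            if prof.target == metabolite_id:
                return prof
        mclass = self.panel.class_of(metabolite_id)
        for prof in self.profiles:
            if prof.target == mclass:
                return prof
        return None

    def expected_log_shift(
        self, metabolite_id: str, temperature: str, delay_h: float, rate: float = 1.0
    ) -> float:
        """Implanted log shift incl. the coupled diacyl-PC deduction.

        ``rate`` is the donor's degradation-rate factor (1 = median donor).
        """
        prof = self.profile_for(metabolite_id)
        shift = rate * prof.log_shift(temperature, delay_h) if prof is not None else 0.0
        if metabolite_id in self.coupling_pool:
            shift += np.log(self._coupling_factor(metabolite_id, temperature, delay_h, rate))
        return shift

    def _coupling_gain(self, temperature: str, delay_h: float, rate: float) -> float:
        """Total molar lysoPC gain (uM) under one condition."""
        gain = 0.0
        for prof in self.profiles:
            if not prof.coupling or prof.target not in self.baseline:
                continue
            shift = rate * prof.log_shift(temperature, delay_h)
            gain += self.baseline[prof.target] * (np.exp(shift) - 1.0)
        return gain

    def _coupling_factor(
        self, metabolite_id: str, temperature: str, delay_h: float, rate: float = 1.0
    ) -> float:
        """Mass-conserving shrink factor for one diacyl-PC pool member.

        The gain is distributed over the pool proportionally to baseline
        times susceptibility, so the summed deduction equals the lysoPC
        gain while species decline at different relative rates.
        """
        weight = sum(
            self.baseline[m] * self.coupling_susceptibility.get(m, 1.0)
            for m in self.coupling_pool
        )
        if weight <= 0:
            return 1.0
        gain = self._coupling_gain(temperature, delay_h, rate)
        s_m = self.coupling_susceptibility.get(metabolite_id, 1.0)
        return max(1.0 - gain * s_m / weight, 0.05)

    def expected_concentration(
        self, metabolite_id: str, temperature: str = "dry_ice", delay_h: float = 0.0
    ) -> float:
        """Expected concentration (uM) under one handling condition.

        Includes the log-normal mean correction for donor and residual
        variance, which is identical across conditions; the treatment shift
        is evaluated at the median degradation rate.
        """
        v = (
            self.sd_between**2
            + self.specific_sd(metabolite_id) ** 2
            + self.sd_class**2
            + self.subject_noise_sd(metabolite_id) ** 2
        )
        shift = self.expected_log_shift(metabolite_id, temperature, delay_h)
        return self.baseline[metabolite_id] * np.exp(shift + v / 2.0)


# ---------------------------------------------------------------------------


def _subject_annotations(config: GeneratorConfig) -> list[SampleAnnotation]:
    anns = []
    per_plate = int(np.ceil(config.n_participants / config.n_plates))
    for i in range(config.n_participants):
        pid = str(i + 1)
        plate = f"P{i // per_plate + 1}"
        anns.append(SampleAnnotation(f"{pid}-ref", pid, "reference", "n/a", 0, 1, plate))
        for temp in ("dry_ice", "wet_ice", "rt"):
            for delay in (12, 24, 36):
                anns.append(
                    SampleAnnotation(
                        f"{pid}-{TEMP_SHORT[temp]}-{delay}h",
                        pid, "handling", temp, delay, 1, plate,
                    )
                )
        for thaws in (2, 3, 4):
            anns.append(
                SampleAnnotation(f"{pid}-ftc{thaws}", pid, "ftc", "n/a", 0, thaws, plate)
            )
    for p in range(config.n_plates):
        plate = f"P{p + 1}"
        for j in range(config.pool_per_plate):
            anns.append(
                SampleAnnotation(f"pool-{plate}-{j + 1}", "pool", "pool", "n/a", 0, 1, plate)
            )
        for j in range(config.zero_per_plate):
            anns.append(
                SampleAnnotation(f"zero-{plate}-{j + 1}", "blank", "zero", "n/a", 0, 1, plate)
            )
    return anns


def generate_study(config: GeneratorConfig) -> ConcentrationDataset:
    """Simulate one full study; deterministic given ``config.seed``."""
    panel = config.panel
    mets = panel.ids
    M = len(mets)
    anns = _subject_annotations(config)
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_shared = np.random.default_rng(streams[0])
    rng_specific = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    rng_pool = np.random.default_rng(streams[3])
    rng_zero = np.random.default_rng(streams[4])
    rng_rate = np.random.default_rng(streams[5])
    rng_class = np.random.default_rng(streams[6])

    base = np.array([config.baseline[m] for m in mets])
    log_base = np.log(base)
    noise_sd = np.array([config.subject_noise_sd(m) for m in mets])
    D = config.n_participants

    # donor intercepts: shared per-sample scale + metabolite-specific part
    # (largest for lipid species) + optional per-class composition effect
    shared = rng_shared.normal(0.0, config.sd_between, D)
    spec_sd = np.array([config.specific_sd(m) for m in mets])
    specific = rng_specific.normal(0.0, 1.0, (D, M)) * spec_sd
    classes = [panel.class_of(m) for m in mets]
    class_names = sorted(set(classes))
    class_eff = rng_class.normal(0.0, config.sd_class, (D, len(class_names)))
    class_col = np.array([class_names.index(c) for c in classes])
    donor = shared[:, None] + specific + class_eff[:, class_col]

    plate_ids = sorted({a.plate for a in anns})
    plate_eff = {
        p: (
            rng_shared.normal(0.0, config.plate_effect_sd, M)
            if config.plate_effect_sd > 0
            else np.zeros(M)
        )
        for p in plate_ids
    }

    # degradation rates: a donor-level enzymatic-activity scale (fast and
    # slow degraders - the donor-level part makes a slow donor's 24 h and
    # 36 h aliquots jointly hard) times an aliquot-by-metabolite jitter
    # (handling micro-variation between aliquots)
    rates = np.exp(rng_rate.normal(0.0, config.sd_rate, D))

    pool_idx = np.array(
        [k for k, m in enumerate(mets) if m in set(config.coupling_pool)], dtype=int
    )
    riser_idx = np.array(
        [
            k
            for k, m in enumerate(mets)
            if (p := config.profile_for(m)) is not None and p.coupling
        ],
        dtype=int,
    )
    pool_total = base[pool_idx].sum() if pool_idx.size else 0.0
    profs = [config.profile_for(m) for m in mets]
    base_shift = {
        (temp, delay): np.array(
            [p.log_shift(temp, delay) if p is not None else 0.0 for p in profs]
        )
        for temp in ("dry_ice", "wet_ice", "rt")
        for delay in (12, 24, 36)
    }

    susc = np.array(
        [config.coupling_susceptibility.get(mets[k], 1.0) for k in pool_idx]
    )
    pool_weight = float(np.sum(base[pool_idx] * susc)) if pool_idx.size else 0.0

    def cond_shift(temp: str, delay: int, d: int) -> np.ndarray:
        # combined donor x aliquot degradation-rate factor, bounded so that
        # exponential trajectories cannot produce implausible outliers
        jitter = np.exp(rng_rate.normal(0.0, config.sd_rate_aliquot, M))
        rate = np.clip(rates[d] * jitter, 1.0 / config.rate_cap, config.rate_cap)
        shift = rate * base_shift[(temp, delay)]
        if pool_idx.size and riser_idx.size and pool_weight > 0:
            gain = float(
                np.sum(base[riser_idx] * (np.exp(shift[riser_idx]) - 1.0))
            )
            f = np.maximum(1.0 - gain * susc / pool_weight, 0.05)
            shift[pool_idx] += np.log(f)
        return shift

    ftc = np.array([config.ftc_slope.get(m, 0.0) for m in mets])

    zero_floor = np.array(
        [
            config.baseline[m]
            * (
                config.qc_fail_zero_frac
                if m in set(config.qc_fail_lod)
                else config.zero_floor_frac
            )
            for m in mets
        ]
    )
    pool_sd = np.array(
        [
            config.qc_fail_pool_sd if m in set(config.qc_fail_cv) else config.noise_sd(m)
            for m in mets
        ]
    )

    rows = np.empty((len(anns), M))
    for i, a in enumerate(anns):
        if a.role == "pool":
            rows[i] = np.exp(
                log_base + plate_eff[a.plate] + rng_pool.normal(0.0, 1.0, M) * pool_sd
            )
        elif a.role == "zero":
            rows[i] = zero_floor * np.exp(rng_zero.normal(0.0, 0.3, M))
        else:
            d = int(a.participant) - 1
            shift = np.zeros(M)
            if a.role == "handling":
                shift = cond_shift(a.temperature, a.delay_h, d)
            log_x = (
                log_base
                + plate_eff[a.plate]
                + donor[d]
                + shift
                + ftc * (a.thaw_count - 1)
                + rng_noise.normal(0.0, 1.0, M) * noise_sd
            )
            rows[i] = np.exp(log_x)

    values = pd.DataFrame(rows, index=[a.sample_id for a in anns], columns=mets)
    return ConcentrationDataset(panel, anns, values)


# ---------------------------------------------------------------------------
# worked fixture: tiny, fully hand-written dataset


def generate_worked_fixture() -> ConcentrationDataset:
    """Deterministic 2-participant, 6-metabolite dataset with hand-set values.

    Built to exercise the QC filters (``C2`` sits below its detection limit;
    ``PC(O-34:1)`` has a noisy pool), the sum ratios, and classification-rule
    arithmetic.  Every number is a literal; calls always return identical
    data.  One cell (participant 2, dry ice 36 h, ``PC(O-34:1)``) is missing.
    """
    panel = build_p150_panel().subset(
        ["Gln", "Ser", "C2", "PC(34:2)", "PC(O-34:1)", "lysoPC(18:0)"]
    )
    mets = panel.ids  # panel order: Gln, Ser, C2, PC(34:2), PC(O-34:1), lysoPC(18:0)

    base = {
        "1": {"Gln": 600.0, "Ser": 100.0, "C2": 5.0, "PC(34:2)": 220.0,
              "PC(O-34:1)": 12.0, "lysoPC(18:0)": 20.0},
        "2": {"Gln": 480.0, "Ser": 80.0, "C2": 7.0, "PC(34:2)": 180.0,
              "PC(O-34:1)": 10.0, "lysoPC(18:0)": 16.0},
    }
    rt_mult = {  # hand-set degradation multipliers at room temperature
        "Gln": {12: 0.97, 24: 0.93, 36: 0.88},
        "Ser": {12: 1.15, 24: 1.35, 36: 1.60},
        "PC(34:2)": {12: 0.95, 24: 0.85, 36: 0.75},
        "lysoPC(18:0)": {12: 1.30, 24: 1.80, 36: 2.40},
    }
    wet_mult_36 = {"Ser": 1.05, "lysoPC(18:0)": 1.05}

    anns: list[SampleAnnotation] = []
    data: list[list[float]] = []

    def add(sid, pid, role, temp, delay, thaws, vals):
        anns.append(SampleAnnotation(sid, pid, role, temp, delay, thaws, "P1"))
        data.append([vals[m] for m in mets])

    for pid in ("1", "2"):
        b = base[pid]
        add(f"{pid}-ref", pid, "reference", "n/a", 0, 1, b)
        for temp in ("dry_ice", "wet_ice", "rt"):
            for delay in (12, 24, 36):
                vals = dict(b)
                if temp == "rt":
                    for m, mult in rt_mult.items():
                        vals[m] = b[m] * mult[delay]
                elif temp == "wet_ice" and delay == 36:
                    for m, mult in wet_mult_36.items():
                        vals[m] = b[m] * mult
                add(f"{pid}-{TEMP_SHORT[temp]}-{delay}h", pid, "handling",
                    temp, delay, 1, vals)
        for thaws in (2, 3, 4):
            add(f"{pid}-ftc{thaws}", pid, "ftc", "n/a", 0, thaws, b)

    pools = {
        "Gln": [500.0, 510.0, 490.0, 500.0],
        "Ser": [100.0, 102.0, 98.0, 100.0],
        "C2": [6.0, 6.0, 6.0, 6.0],
        "PC(34:2)": [200.0, 210.0, 190.0, 200.0],
        "PC(O-34:1)": [10.0, 18.0, 6.0, 14.0],   # CV 0.43: fails the 25% rule
        "lysoPC(18:0)": [25.0, 26.0, 24.0, 25.0],
    }
    for j in range(4):
        add(f"pool-P1-{j + 1}", "pool", "pool", "n/a", 0, 1,
            {m: pools[m][j] for m in mets})

    zeros = {
        "Gln": [1.0, 1.0, 1.0],
        "Ser": [0.5, 0.5, 0.5],
        "C2": [2.0, 3.0, 4.0],       # LOD 9 uM: all subject values sit below
        "PC(34:2)": [0.2, 0.2, 0.2],
        "PC(O-34:1)": [0.1, 0.1, 0.1],
        "lysoPC(18:0)": [0.1, 0.2, 0.3],
    }
    for j in range(3):
        add(f"zero-P1-{j + 1}", "blank", "zero", "n/a", 0, 1,
            {m: zeros[m][j] for m in mets})

    values = pd.DataFrame(data, index=[a.sample_id for a in anns], columns=mets)
    values.loc["2-dry-36h", "PC(O-34:1)"] = np.nan
    return ConcentrationDataset(panel, anns, values)
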
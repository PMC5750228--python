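"""Scenario definitions for synthetic biocrust wet-up experiments.

A :class:`WetupScenario` describes a laboratory wetting experiment on
biological soil crust: a panel of focal taxa with hydration-response
curves, a panel of soil-water metabolites with leaching/release/uptake
kinetics, the sampling design (successional stages x time points x
replicates, plus killed controls), and the observation model (peak-area
gain, multiplicative noise, sequencing depth).

The default scenario emulates a typical wet-up design: four successional
stages (A, young/light .. D, mature/dark), five time points from 3 min
(0.05 h) to 49.5 h, five active replicates per cell (100 active samples)
and triplicate killed controls from a late-stage crust. The four focal
taxa follow the canonical wet-up cascade: an early-responding filamentous
autotroph, a mid-wetup heterotrophic bloomer, a late-wetup heterotroph,
and a wetting-indifferent taxon whose abundance is graded across the
successional axis instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

RESPONDER_CLASSES = ("early", "mid", "late", "flat")
DEFAULT_STAGES = ("A", "B", "C", "D")
#: Sampling times in hours; the first point encodes "3 minutes".
DEFAULT_TIME_POINTS = (0.05, 9.0, 18.0, 42.0, 49.5)


@dataclass(frozen=True)
class TaxonSpec:
    """Hydration-response curve of one focal taxon.

    Abundance over time ``t`` (hours) in stage ``s`` is the log-time
    Gaussian ``scale(s) * (baseline + amplitude *
    exp(-(ln t - ln peak_time)^2 / (2 * peak_width^2)))``, so an "early"
    responder can peak at the first sampled time while abundance stays
    positive and smooth on the hour scale.

    Parameters
    ----------
    taxon_id : str
        Unique label.
    responder_class : {"early", "mid", "late", "flat"}
        Qualitative wet-up response; ``flat`` taxa must have zero
        amplitude (their abundance varies only across stages).
    peak_time : float
        Hours after wetting at which abundance peaks; must lie within
        the simulation horizon.
    peak_width : float
        Standard deviation of the peak on the log-time axis
        (dimensionless).
    baseline, amplitude : float
        Abundance units (arbitrary biomass scale), both >= 0.
    succession_scale : mapping stage -> float
        Per-stage multiplier >= 0 applied to the whole curve.
    """

    taxon_id: str
    responder_class: str
    peak_time: float
    peak_width: float
    baseline: float
    amplitude: float
    succession_scale: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in DEFAULT_STAGES}
    )

    def __post_init__(self) -> None:
        if self.responder_class not in RESPONDER_CLASSES:
            raise ValueError(
                f"{self.taxon_id}: responder_class must be one of "
                f"{RESPONDER_CLASSES}, got {self.responder_class!r}"
            )
        if self.peak_time <= 0:
            raise ValueError(f"{self.taxon_id}: peak_time must be > 0")
        if self.peak_width <= 0:
            raise ValueError(f"{self.taxon_id}: peak_width must be > 0")
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError(f"{self.taxon_id}: baseline/amplitude must be >= 0")
        if self.responder_class == "flat" and self.amplitude != 0:
            raise ValueError(f"{self.taxon_id}: flat taxa must have amplitude 0")
        if any(v < 0 for v in self.succession_scale.values()):
            raise ValueError(f"{self.taxon_id}: succession_scale must be >= 0")


@dataclass(frozen=True)
class MetaboliteSpec:
    """Mass-balance parameters for one soil-water metabolite.

    The pool follows
    ``dM/dt = leach_rate * exp(-t / leach_decay)
    + sum_i release_rate[i] * B_i(t)
    - sum_i uptake_rate[i] * B_i(t) * M / (half_saturation + M)``,
    i.e. first-order abiotic leaching from the crust matrix plus
    biomass-proportional release and Monod-type microbial uptake.

    Units: pools in concentration units; ``release_rate`` in
    concentration/(abundance*hour); ``uptake_rate`` in
    1/(abundance*hour); ``half_saturation`` in concentration units.
    """

    metabolite_id: str
    initial_pool: float
    leach_rate: float = 0.0
    leach_decay: float = 10.0
    release_rate: Mapping[str, float] = field(default_factory=dict)
    uptake_rate: Mapping[str, float] = field(default_factory=dict)
    half_saturation: float = 1.0
    putative: bool = False

    def __post_init__(self) -> None:
        if self.initial_pool < 0:
            raise ValueError(f"{self.metabolite_id}: initial_pool must be >= 0")
        if self.leach_rate < 0:
            raise ValueError(f"{self.metabolite_id}: leach_rate must be >= 0")
        if self.leach_decay <= 0:
            raise ValueError(f"{self.metabolite_id}: leach_decay must be > 0")
        if self.half_saturation <= 0:
            raise ValueError(f"{self.metabolite_id}: half_saturation must be > 0")
        for name, rates in (("release", self.release_rate), ("uptake", self.uptake_rate)):
            for taxon, r in rates.items():
                if not (r >= 0 and r == r and r != float("inf")):
                    raise ValueError(
                        f"{self.metabolite_id}: {name} rate for {taxon} "
                        "must be finite and >= 0"
                    )

    def expected_sign(self, taxon_id: str) -> int:
        """Ground-truth correlation sign for a (taxon, metabolite) pair.

        -1 if the taxon only takes the metabolite up, +1 if it only
        releases it, 0 otherwise (neither, or both).
        """
        u = self.uptake_rate.get(taxon_id, 0.0)
        r = self.release_rate.get(taxon_id, 0.0)
        if u > 0 and r == 0:
            return -1
        if r > 0 and u == 0:
            return +1
        return 0


@dataclass
class WetupScenario:
    """Complete generative description of a synthetic wet-up data set."""

    taxa: Sequence[TaxonSpec]
    metabolites: Sequence[MetaboliteSpec]
    stages: Sequence[str] = DEFAULT_STAGES
    time_points: Sequence[float] = DEFAULT_TIME_POINTS
    replicates_active: int = 5
    replicates_killed: int = 3
    killed_stage: str = "D"
    #: log-scale SD of multiplicative peak-area observation noise.
    noise_sigma: float = 0.25
    #: peak areas below this are recorded as missing.
    detection_limit: float = 0.0
    #: marker reads per metagenome sample.
    read_depth: int = 20_000
    seed: int = 0
    #: peak-area counts per concentration unit.
    gain: float = 1.0e5
    #: abundance of the unmodeled "background" community.
    background_abundance: float = 20.0
    #: forward-Euler step for metabolite integration, hours.
    euler_step: float = 0.05
    #: effective biomass and duration of the isolate spent-media culture.
    culture_biomass: float = 3.0
    culture_hours: float = 24.0
    #: log-scale SD of fold-change noise in spent-media profiles.
    exo_noise_sigma: float = 0.2
    #: marker-gene length (nt) and isolate-vs-environment divergence.
    marker_length: int = 450
    isolate_divergence: float = 0.10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tp = list(self.time_points)
        if any(t <= 0 for t in tp):
            raise ValueError("time points must be positive (3 min == 0.05 h)")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.killed_stage not in self.stages:
            raise ValueError(f"killed_stage {self.killed_stage!r} not in stages")
        if self.replicates_active < 1 or self.replicates_killed < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sigma < 0 or self.detection_limit < 0:
            raise ValueError("noise_sigma and detection_limit must be >= 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.euler_step <= 0:
            raise ValueError("euler_step must be > 0")
        if not (0 <= self.isolate_divergence <= 1):
            raise ValueError("isolate_divergence must be in [0, 1]")
        horizon = max(tp)
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")
        mids = [m.metabolite_id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ValueError("metabolite ids must be unique")
        for t in self.taxa:
            if t.responder_class != "flat" and t.peak_time > horizon:
                raise ValueError(
                    f"{t.taxon_id}: peak_time {t.peak_time} outside horizon {horizon}"
                )
            missing = set(self.stages) - set(t.succession_scale)
            if missing:
                raise ValueError(f"{t.taxon_id}: no succession_scale for {missing}")
        known = set(ids)
        for m in self.metabolites:
            for taxon in list(m.release_rate) + list(m.uptake_rate):
                if taxon not in known:
                    raise ValueError(
                        f"{m.metabolite_id}: rate refers to unknown taxon {taxon!r}"
                    )

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.metabolite_id for m in self.metabolites]

    def expected_signs(self) -> dict[tuple[str, str], int]:
        """Ground-truth sign for every (taxon, metabolite) pair."""
        return {
            (t.taxon_id, m.metabolite_id): m.expected_sign(t.taxon_id)
            for t in self.taxa
            for m in self.metabolites
        }

    # ------------------------------------------------------------------
    # serialization

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["time_points"] = list(self.time_points)
        d["taxa"] = [dict(asdict(t)) for t in self.taxa]
        d["metabolites"] = [dict(asdict(m)) for m in self.metabolites]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WetupScenario":
        d = dict(d)
        d["taxa"] = [TaxonSpec(**t) for t in d.get("taxa", [])]
        d["metabolites"] = [MetaboliteSpec(**m) for m in d.get("metabolites", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WetupScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_taxa() -> list[TaxonSpec]:
    """Four focal taxa spanning the wet-up response cascade."""
    return [
        TaxonSpec(
            "cyano_early", "early", peak_time=0.05, peak_width=1.0,
            baseline=0.05, amplitude=8.0,
            succession_scale={"A": 1.3, "B": 1.15, "C": 1.0, "D": 0.85},
        ),
        TaxonSpec(
            "firmicute_mid", "mid", peak_time=18.0, peak_width=0.8,
            baseline=0.3, amplitude=6.0,
            succession_scale={"A": 0.9, "B": 1.0, "C": 1.15, "D": 1.0},
        ),
        TaxonSpec(
            "firmicute_late", "late", peak_time=42.0, peak_width=0.7,
            baseline=0.2, amplitude=3.0,
            succession_scale={"A": 0.8, "B": 0.9, "C": 1.2, "D": 1.1},
        ),
        TaxonSpec(
            "actino_flat", "flat", peak_time=1.0, peak_width=1.0,
            baseline=1.0, amplitude=0.0,
            succession_scale={"A": 0.5, "B": 0.8, "C": 1.25, "D": 1.6},
        ),
    ]


def default_metabolites() -> list[MetaboliteSpec]:
    """Twelve metabolites spanning released-only, consumed-only,
    released-and-consumed, and abiotic-only dynamics.

    The early autotroph tops up sugar pools that start high (leached at
    wet-up) and are drawn down from the start by the wetting-indifferent
    taxon and, late, by the late heterotroph; the mid heterotroph
    releases nucleobase-like byproducts that the late responder
    consumes; the late responder consumes amino acids and releases a
    purine byproduct; the flat taxon additionally consumes substrates
    whose depletion is graded across the successional axis.
    """
    return [
        MetaboliteSpec("glucose", initial_pool=5.0,
                       release_rate={"cyano_early": 0.15},
                       uptake_rate={"actino_flat": 0.12,
                                    "firmicute_late": 0.20}),
        MetaboliteSpec("sucrose", initial_pool=6.0,
                       release_rate={"cyano_early": 0.18},
                       uptake_rate={"actino_flat": 0.14,
                                    "firmicute_late": 0.25}),
        MetaboliteSpec("uracil", initial_pool=0.1,
                       release_rate={"firmicute_mid": 0.02},
                       uptake_rate={"firmicute_late": 0.50}),
        MetaboliteSpec("hypoxanthine", initial_pool=0.1,
                       release_rate={"firmicute_mid": 0.03},
                       uptake_rate={"firmicute_late": 0.55}),
        MetaboliteSpec("glutamate", initial_pool=5.0,
                       uptake_rate={"firmicute_late": 0.15}),
        MetaboliteSpec("glycine", initial_pool=4.0,
                       uptake_rate={"firmicute_late": 0.12}),
        MetaboliteSpec("xanthine", initial_pool=0.2,
                       release_rate={"firmicute_late": 0.10}),
        MetaboliteSpec("trehalose", initial_pool=6.0,
                       uptake_rate={"actino_flat": 0.08}),
        MetaboliteSpec("adenine", initial_pool=5.0,
                       uptake_rate={"actino_flat": 0.06}),
        MetaboliteSpec("proline", initial_pool=5.0,
                       uptake_rate={"actino_flat": 0.05}),
        MetaboliteSpec("salicylate", initial_pool=0.5,
                       leach_rate=0.08, leach_decay=30.0, putative=True),
        MetaboliteSpec("ergothioneine", initial_pool=1.0,
                       leach_rate=0.01, leach_decay=20.0),
    ]


def default_scenario(seed: int = 0, **overrides) -> WetupScenario:
    """The package's reference synthetic wet-up scenario.

    4 focal taxa x 12 metabolites, 4 stages x 5 time points x 5 active
    replicates (100 active samples) with triplicate stage-D killed
    controls, multiplicative observation noise (CV ~ 25%) and 20k marker
    reads per metagenome sample.
    """
    overrides.setdefault("taxa", default_taxa())
    overrides.setdefault("metabolites", default_metabolites())
    return WetupScenario(seed=seed, **overrides)
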
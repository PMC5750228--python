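"""Synthetic wet-up data generation.

Produces, from a :class:`~crustlink.scenario.WetupScenario`, everything
the downstream pipeline ingests: taxon abundance trajectories, metabolite
pool dynamics (active and killed), noisy replicated peak-area tables,
multinomial marker-gene read counts, isolate spent-media exometabolite
profiles, and marker-gene FASTA records for both environmental taxa and
their matching isolates — together with the generating ground truth.

All randomness flows from the scenario's root seed through named
substreams so that identical scenarios yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolome import PeakAreaTable
from .scenario import WetupScenario

# named substreams off the root seed
_STREAM_AREAS_ACTIVE = 1
_STREAM_AREAS_KILLED = 2
_STREAM_READS = 3
_STREAM_EXO = 4
_STREAM_MARKERS = 5

_BACKGROUND = "background"
_BASES = np.array(list("ACGT"))


def _rng(scenario: WetupScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed) % (2**31), stream])


def _group_columns(scenario: WetupScenario) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(scenario.stages), list(scenario.time_points)],
        names=["stage", "time"],
    )


def abundance_curve(taxon, times: np.ndarray) -> np.ndarray:
    """Closed-form log-time Gaussian response, unscaled by stage.

    ``B(t) = baseline + amplitude * exp(-(ln t - ln peak)^2 / (2 w^2))``
    with ``B(0) = baseline`` as the t -> 0 limit.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative time point")
    out = np.full(times.shape, float(taxon.baseline))
    pos = times > 0
    z = (np.log(times[pos]) - math.log(taxon.peak_time)) / taxon.peak_width
    out[pos] = taxon.baseline + taxon.amplitude * np.exp(-0.5 * z**2)
    return out


def simulate_abundance(scenario: WetupScenario) -> pd.DataFrame:
    """Deterministic taxon x (stage, time) abundance matrix."""
    times = np.asarray(scenario.time_points, dtype=float)
    if (times <= 0).any():
        raise ValueError("time points must be positive")
    cols = _group_columns(scenario)
    rows = {}
    for t in scenario.taxa:
        base = abundance_curve(t, times)
        rows[t.taxon_id] = np.concatenate(
            [base * t.succession_scale[s] for s in scenario.stages]
        )
    return pd.DataFrame(rows, index=cols).T


def simulate_metabolites(
    scenario: WetupScenario, killed: bool = False, step: float | None = None
) -> pd.DataFrame:
    """Forward-Euler integration of the metabolite mass balance.

    ``dM/dt = leach + release - Monod uptake`` (see
    :class:`~crustlink.scenario.MetaboliteSpec`); in killed mode all
    biological terms vanish and only abiotic leaching remains. Pools are
    clamped at zero. Returns metabolite x (stage, time) pools at the
    sampled time points.
    """
    dt = scenario.euler_step if step is None else float(step)
    if dt <= 0:
        raise ValueError("step size must be positive")
    times = np.asarray(scenario.time_points, dtype=float)
    n_steps = int(round(times.max() / dt))
    grid = np.arange(n_steps + 1) * dt
    # indices of sample times on the grid (nearest step)
    sample_idx = np.array([int(round(t / dt)) for t in times])

    mets = scenario.metabolites
    n_m = len(mets)
    taxa = scenario.taxa
    leach0 = np.array([m.leach_rate for m in mets])
    decay = np.array([m.leach_decay for m in mets])
    K = np.array([m.half_saturation for m in mets])
    R = np.array([[m.release_rate.get(t.taxon_id, 0.0) for t in taxa] for m in mets])
    U = np.array([[m.uptake_rate.get(t.taxon_id, 0.0) for t in taxa] for m in mets])

    cols = _group_columns(scenario)
    out = np.empty((n_m, len(cols)))
    for si, stage in enumerate(scenario.stages):
        if killed:
            B = np.zeros((len(taxa), n_steps + 1))
        else:
            B = np.vstack([
                abundance_curve(t, grid) * t.succession_scale[stage] for t in taxa
            ])
        M = np.array([m.initial_pool for m in mets], dtype=float)
        sampled = {}
        if 0 in sample_idx:
            sampled[0] = M.copy()
        leach_t = leach0[:, None] * np.exp(-grid[None, :] / decay[:, None])
        for k in range(n_steps):
            b = B[:, k]
            dM = leach_t[:, k] + R @ b - (U @ b) * M / (K + M)
            M = np.maximum(M + dt * dM, 0.0)
            if (k + 1) in sample_idx:
                sampled[k + 1] = M.copy()
        for ti, idx in enumerate(sample_idx):
            out[:, si * len(times) + ti] = sampled[idx]
    return pd.DataFrame(out, index=[m.metabolite_id for m in mets], columns=cols)


def observe_peak_areas(
    pools: pd.DataFrame,
    scenario: WetupScenario,
    condition: str = "active",
    stages=None,
    n_replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> PeakAreaTable:
    """Turn true pools into a replicated, noisy peak-area table.

    Per replicate, ``area = gain * M * exp(eps)`` with
    ``eps ~ N(0, noise_sigma^2)``; areas below the detection limit are
    recorded as missing. Sample metadata (stage, time, replicate,
    condition, qc_pass) is populated alongside.
    """
    if condition == "active":
        stages = list(scenario.stages) if stages is None else list(stages)
        n_rep = scenario.replicates_active if n_replicates is None else n_replicates
        stream = _STREAM_AREAS_ACTIVE
    else:
        stages = [scenario.killed_stage] if stages is None else list(stages)
        n_rep = scenario.replicates_killed if n_replicates is None else n_replicates
        stream = _STREAM_AREAS_KILLED
    if rng is None:
        rng = _rng(scenario, stream)

    sample_ids, meta_rows, columns = [], [], []
    for stage in stages:
        for t in scenario.time_points:
            true = pools[(stage, t)].to_numpy(dtype=float)
            for rep in range(1, n_rep + 1):
                eps = rng.normal(0.0, scenario.noise_sigma, size=true.shape)
                area = scenario.gain * true * np.exp(eps)
                area = np.where(area < scenario.detection_limit, np.nan, area)
                sid = f"{condition}-{stage}-{t:g}h-r{rep}"
                sample_ids.append(sid)
                meta_rows.append((t, stage, rep, condition, True))
                columns.append(area)
    areas = pd.DataFrame(
        np.column_stack(columns), index=pools.index, columns=sample_ids
    )
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(sample_ids, name="sample_id"),
        columns=["time", "stage", "replicate", "condition", "qc_pass"],
    )
    return PeakAreaTable(areas, meta)


def simulate_marker_reads(
    abundances: pd.DataFrame,
    scenario: WetupScenario,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial marker-gene read counts, one metagenome per group.

    A constant "background" taxon absorbs the unmodeled community so
    focal relative abundances stay well below 1. Counts in each sample
    sum to ``read_depth``.
    """
    if scenario.read_depth <= 0:
        raise ValueError("read_depth must be > 0")
    if rng is None:
        rng = _rng(scenario, _STREAM_READS)
    full = abundances.copy()
    full.loc[_BACKGROUND] = scenario.background_abundance
    counts = np.empty(full.shape, dtype=int)
    vals = full.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        tot = col.sum()
        if tot <= 0:
            raise ValueError(
                f"all-zero abundance vector in sample {full.columns[j]}"
            )
        counts[:, j] = rng.multinomial(scenario.read_depth, col / tot)
    return pd.DataFrame(counts, index=full.index, columns=full.columns)


def random_marker(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_marker(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` (always to a
    different base)."""
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < divergence
    for i in np.where(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def simulate_markers(
    scenario: WetupScenario, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Random environmental marker genes plus isolate versions mutated
    at the configured per-site divergence.

    Returns ``(environmental, isolates)`` keyed by taxon id and
    ``iso-<taxon id>`` respectively.
    """
    if rng is None:
        rng = _rng(scenario, _STREAM_MARKERS)
    env = {t.taxon_id: random_marker(scenario.marker_length, rng)
           for t in scenario.taxa}
    iso = {
        f"iso-{tid}": mutate_marker(seq, scenario.isolate_divergence, rng)
        for tid, seq in env.items()
    }
    return env, iso


def isolate_fold_change(
    uptake: float, release: float, initial_pool: float, scenario: WetupScenario
) -> float:
    """Noise-free spent-media fold-change for one (isolate, metabolite).

    ``fc = exp(-u * c_b * T_c) * (1 + r * c_b * T_c / M0)`` where
    ``c_b`` is the effective culture biomass and ``T_c`` the culture
    duration: first-order depletion by uptake plus linear accumulation
    of released material relative to the defined-medium starting pool.
    """
    if initial_pool == 0 and release > 0:
        raise ValueError("release into a zero starting pool is undefined")
    ct = scenario.culture_biomass * scenario.culture_hours
    fc = math.exp(-uptake * ct)
    if release > 0:
        fc *= 1.0 + release * ct / initial_pool
    return fc


def simulate_exoprofiles(
    scenario: WetupScenario,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spent-media exometabolite table for one isolate per focal taxon.

    Returns a long DataFrame with isolate_id, metabolite_id, mean
    inoculated and control peak areas, the realized fold-change and the
    ground-truth class implied by the noise-free fold-change.
    """
    from . import exoprofile as xp

    if rng is None:
        rng = _rng(scenario, _STREAM_EXO)
    rows = []
    for t in scenario.taxa:
        iso = f"iso-{t.taxon_id}"
        for m in scenario.metabolites:
            u = m.uptake_rate.get(t.taxon_id, 0.0)
            r = m.release_rate.get(t.taxon_id, 0.0)
            fc0 = isolate_fold_change(u, r, m.initial_pool, scenario)
            fc = fc0
            if noise and scenario.exo_noise_sigma > 0:
                fc = fc0 * math.exp(rng.normal(0.0, scenario.exo_noise_sigma))
            control = scenario.gain * m.initial_pool
            rows.append({
                "isolate_id": iso,
                "metabolite_id": m.metabolite_id,
                "mean_area_inoculated": fc * control,
                "mean_area_control": control,
                "fold_change": fc,
                "true_class": xp.classify(fc0),
            })
    return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """One complete synthetic wet-up study with its ground truth."""

    scenario: WetupScenario
    true_abundance: pd.DataFrame
    true_pools_active: pd.DataFrame
    true_pools_killed: pd.DataFrame
    active: PeakAreaTable
    killed: PeakAreaTable
    marker_counts: pd.DataFrame
    marker_catalog: dict[str, pd.DataFrame]
    env_markers: dict[str, str]
    isolate_markers: dict[str, str]
    spent_media: pd.DataFrame
    expected_sign: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def isolate_to_taxon(self) -> dict[str, str]:
        """Generating isolate -> taxon map (ground truth, not inferred)."""
        return {f"iso-{tid}": tid for tid in self.scenario.taxon_ids}


def simulate_dataset(scenario: WetupScenario) -> SimulatedDataset:
    """Generate the full study: tables, reads, markers, profiles, truth.

    The marker catalog holds two ribosomal-protein families: the primary
    family ("rplO") with one assembled gene per focal taxon plus the
    background bin, and a sparser family ("rpsC") missing one taxon —
    so that coverage-based family selection is exercised downstream.
    """
    abund = simulate_abundance(scenario)
    pools_a = simulate_metabolites(scenario, killed=False)
    pools_k = simulate_metabolites(scenario, killed=True)
    active = observe_peak_areas(pools_a, scenario, condition="active")
    killed = observe_peak_areas(pools_k, scenario, condition="killed")
    reads = simulate_marker_reads(abund, scenario)
    env, iso = simulate_markers(scenario)
    spent = simulate_exoprofiles(scenario)
    catalog = {"rplO": reads, "rpsC": reads.drop(index=reads.index[-2])}
    return SimulatedDataset(
        scenario=scenario,
        true_abundance=abund,
        true_pools_active=pools_a,
        true_pools_killed=pools_k,
        active=active,
        killed=killed,
        marker_counts=reads,
        marker_catalog=catalog,
        env_markers=env,
        isolate_markers=iso,
        spent_media=spent,
        expected_sign=scenario.expected_signs(),
    )
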
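import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crustlink import default_scenario, simulate_dataset
from crustlink.metabolome import PeakAreaTable
from crustlink.scenario import MetaboliteSpec, TaxonSpec, WetupScenario

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def dataset(scenario):
    return simulate_dataset(scenario)


def flat_taxon(taxon_id="bug", baseline=1.0, stages=("A",)):
    return TaxonSpec(
        taxon_id, "flat", peak_time=1.0, peak_width=1.0,
        baseline=baseline, amplitude=0.0,
        succession_scale={s: 1.0 for s in stages},
    )


def tiny_scenario(taxa=None, metabolites=None, **kw):
    """Minimal single-stage scenario for unit tests."""
    kw.setdefault("stages", ("A",))
    kw.setdefault("killed_stage", kw["stages"][-1])
    kw.setdefault("noise_sigma", 0.0)
    kw.setdefault("gain", 1.0)
    taxa = [flat_taxon()] if taxa is None else taxa
    metabolites = (
        [MetaboliteSpec("met", initial_pool=10.0)]
        if metabolites is None else metabolites
    )
    return WetupScenario(taxa=taxa, metabolites=metabolites, **kw)


def table_from_cells(cells: pd.DataFrame, n_rep=3, condition="active",
                     qc_fail=()):
    """Replicate a metabolite x (stage, time) cell matrix into an
    exact (noise-free) PeakAreaTable."""
    ids, meta_rows, cols = [], [], []
    for stage, t in cells.columns:
        for rep in range(1, n_rep + 1):
            sid = f"{condition}-{stage}-{t:g}h-r{rep}"
            ids.append(sid)
            meta_rows.append((t, stage, rep, condition, sid not in qc_fail))
            cols.append(cells[(stage, t)].to_numpy(dtype=float))
    areas = pd.DataFrame(np.column_stack(cols), index=cells.index, columns=ids)
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(ids, name="sample_id"),
        columns=["time", "stage", "replicate", "condition", "qc_pass"],
    )
    return PeakAreaTable(areas, meta)


def cell_frame(values: dict, stages=("A",), times=(1.0, 2.0, 3.0)):
    """Build a metabolite x (stage, time) DataFrame from per-metabolite
    value lists laid out stage-major."""
    cols = pd.MultiIndex.from_product([stages, times], names=["stage", "time"])
    return pd.DataFrame(values, index=cols).T
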
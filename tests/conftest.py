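import pytest
from hypothesis import settings

from gipcms.masslist import ChainSpace
from gipcms.simulate import SimConfig, simulate_run

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# A compact, well-populated chain space: one ECN group per (series, R),
# so the retention-model filter is always fitted.
COMPACT_SPACE = ChainSpace(spb_oh=(3,), fa_oh=(0,), total_oh_range=(3, 3))


def compact_config(seed: int, **overrides) -> SimConfig:
    defaults = dict(
        seed=seed,
        n_true=12,
        series_mix=(("B", "NH", 1.0),),
        chain_space=COMPACT_SPACE,
        species_level_fraction=0.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def clean_run():
    """One noise-free-decoy-free synthetic acquisition shared across tests."""
    cfg = compact_config(seed=11, n_true=10)
    truth, runs = simulate_run(cfg)
    return cfg, truth, runs


def isomer_pair_scenario(seed: int = 31):
    """Constructed fixture: the isobaric chain splits 18:0;O3/24:1 and
    18:1;O3/24:0 eluting 0.4 min apart (straddling their common ECN-model
    retention time), plus anchor species defining the retention line.

    Returns (entries, runs, iso_a, iso_b).
    """
    import numpy as np

    from gipcms.chem import ADDUCTS, mz_of
    from gipcms.model import CeramideSpec, GipcSpecies, parse_name
    from gipcms.simulate import TruthEntry, build_runs

    cfg = compact_config(seed=seed, n_true=0)
    entries = []
    for fa_c in (20, 21, 22, 26):
        sp = GipcSpecies("B", "NH",
                         CeramideSpec.molecular(18, 0, 3, fa_c, 0, 0))
        rt = cfg.rt_intercept + cfg.rt_slope * sp.ceramide.ecn
        entries.append(TruthEntry(
            sp, rt, rt,
            mz_of(sp.formula, ADDUCTS["[M+H]+"]),
            mz_of(sp.formula, ADDUCTS["[M-H]-"]), 5e5,
        ))
    iso_a = parse_name("B-NH-18:0;O3/24:1")
    iso_b = parse_name("B-NH-18:1;O3/24:0")
    rt_line = cfg.rt_intercept + cfg.rt_slope * iso_a.ceramide.ecn
    for sp, offset in ((iso_a, -0.2), (iso_b, +0.2)):
        entries.append(TruthEntry(
            sp, rt_line + offset, rt_line + offset,
            mz_of(sp.formula, ADDUCTS["[M+H]+"]),
            mz_of(sp.formula, ADDUCTS["[M-H]-"]), 5e5,
        ))
    runs = build_runs(entries, cfg, np.random.default_rng(seed))
    return entries, runs, iso_a, iso_b
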
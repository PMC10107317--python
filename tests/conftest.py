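import numpy as np
import pandas as pd
import pytest

from rivertrends import glmm, simulate


@pytest.fixture(scope="session")
def tiny_survey():
    """A small complete survey with the default three-guild taxa spec."""
    cfg = simulate.SimulationConfig(
        n_sites=30, p_season_sampled=0.7, sd_olre=0.5, seed=11
    )
    sites = simulate.generate_sites(cfg)
    recs, truth = simulate.generate_survey(sites, cfg)
    return {
        "config": cfg,
        "sites": sites,
        "records": recs,
        "truth": truth,
        "taxonomy": simulate.taxonomy_table(cfg.taxa_spec),
        "traits": simulate.trait_table(cfg.taxa_spec),
    }


def make_model_data(y, t, site_idx, X=None, fixed_names=None):
    """Assemble a ModelData directly from arrays (test scaffolding)."""
    y = np.asarray(y, float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
        fixed_names = ["(Intercept)"]
    years, yidx = np.unique(np.asarray(t, int), return_inverse=True)
    sids, sidx = np.unique(np.asarray(site_idx), return_inverse=True)
    return glmm.ModelData(
        y=y,
        X=np.asarray(X, float),
        fixed_names=list(fixed_names),
        site_idx=sidx,
        n_sites=len(sids),
        site_ids=list(sids),
        year_idx=yidx,
        n_years=len(years),
        years=years,
        t=np.asarray(t, float),
        offset=np.zeros(n),
    )


def sample_csv_text(rows):
    """Render sample-CSV text from (site, sample, date, method, taxon, rank, count)."""
    header = "site_id,sample_id,date,method,taxon_name,taxon_rank,count"
    return "\n".join([header] + [",".join(map(str, r)) for r in rows]) + "\n"
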
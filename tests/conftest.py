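"""Shared fixtures: the fitted pair model and the default synthetic proteome.

The heavy fixtures are session-scoped: the pair model is fitted once on the
synthetic benchmark, and the 50-model proteome is generated, parsed and
classified once and shared across recovery, conservation and summary tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from afdomain import Thresholds, generate_proteome, parse_domains
from afdomain.classify import classify_model, residue_labels
from afdomain.pairmodel import default_pair_model
from afdomain.simulate import make_families


@pytest.fixture(scope="session")
def pair_model():
    return default_pair_model(seed=1)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def proteome50():
    return generate_proteome(50, seed=7)


@pytest.fixture(scope="session")
def classified50(proteome50, pair_model, thresholds):
    """Parse + classify every model of the default proteome.

    Returns a dict with per-model candidates, regions, predicted and true
    per-residue label arrays.
    """
    hits_by = {}
    for h in proteome50.hits:
        hits_by.setdefault(h.query_id, []).append(h)
    out = {"candidates": {}, "regions": {}, "pred": {}, "true": {}, "all_regions": []}
    for model, truth in zip(proteome50.models, proteome50.truths):
        cands, mask = parse_domains(
            model, hits_by.get(model.model_id, []), pair_model, thresholds
        )
        regions = classify_model(model, cands, mask, thresholds)
        out["candidates"][model.model_id] = cands
        out["regions"][model.model_id] = regions
        out["pred"][model.model_id] = residue_labels(regions, model.n_residues)
        out["true"][model.model_id] = truth.label_array()
        out["all_regions"].extend(regions)
    return out


@pytest.fixture(scope="session")
def family_records():
    """Ten sequence families of ten members each (the clustering fixture)."""
    return make_families(10, 10, seed=9)
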
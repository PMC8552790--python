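from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirmarker import ExpressionStudy

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_study(tumor: dict[str, list[float]], normal: dict[str, list[float]], pair: bool = False) -> ExpressionStudy:
    """Small ExpressionStudy from per-miRNA tumor/normal value lists."""
    mirnas = list(tumor)
    n_t = len(next(iter(tumor.values())))
    n_n = len(next(iter(normal.values())))
    t_cols = [f"T{i+1}" for i in range(n_t)]
    n_cols = [f"N{i+1}" for i in range(n_n)]
    data = {c: [tumor[m][i] for m in mirnas] for i, c in enumerate(t_cols)}
    data.update({c: [normal[m][i] for m in mirnas] for i, c in enumerate(n_cols)})
    values = pd.DataFrame(data, index=mirnas, dtype=float)
    labels = pd.Series({**{c: "tumor" for c in t_cols}, **{c: "normal" for c in n_cols}})
    pid = None
    if pair:
        assert n_t == n_n
        pid = pd.Series({**{c: f"P{i+1}" for i, c in enumerate(t_cols)}, **{c: f"P{i+1}" for i, c in enumerate(n_cols)}})
    return ExpressionStudy(values=values, labels=labels, pair_id=pid)


@pytest.fixture
def toy_study() -> ExpressionStudy:
    return make_study(
        tumor={"mir1": [8.0, 8.0], "mir2": [2.0, 3.0], "mir3": [5.0, 7.0]},
        normal={"mir1": [2.0, 2.0], "mir2": [2.0, 3.0], "mir3": [1.0, 3.0]},
        pair=True,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
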
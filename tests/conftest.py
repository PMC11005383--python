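import warnings

import numpy as np
import pandas as pd
import pytest

from tilscale import scales
from tilscale.synthetic import GeneratorConfig, generate_cohort, inject_missingness

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


def random_therapy_record(rng: np.random.Generator) -> dict:
    """A uniformly random daily therapy record (valid levels only)."""
    rec = {}
    for item, levels in scales.ITEM_LEVELS.items():
        if levels == ("present",):
            rec[item] = int(rng.integers(2))
        else:
            rec[item] = str(rng.choice(("none",) + levels))
    return rec


@pytest.fixture(scope="session")
def scale_configs():
    return scales.load_scale_configs()


@pytest.fixture(scope="session")
def small_cohort():
    """A complete 120-patient synthetic cohort with its ground truth."""
    cfg = GeneratorConfig.for_n(120)
    return generate_cohort(cfg, seed=11) + (cfg,)


@pytest.fixture(scope="session")
def masked_cohort(small_cohort):
    """The same cohort with missing-at-random gaps injected."""
    cohort, truth, cfg = small_cohort
    return inject_missingness(cohort, cfg, seed=11), truth, cfg


def brute_force_score(record: dict, config: scales.ScaleConfig) -> int:
    """Independent scorer: enumerate every sub-item of every item.

    Walks the configuration table sub-item by sub-item, collecting the
    score of each administered sub-item, then applies the aggregation
    rule from scratch.  Shares no code with ``score_daily``.
    """
    per_item_scores: dict[str, list[int]] = {}
    for item, levels in scales.ITEM_LEVELS.items():
        val = record.get(item)
        administered = []
        if levels == ("present",):
            if val == 1:
                administered.append("present")
        elif val is not None and val != "none":
            administered.append(val)
        scored = [
            config.subitem_scores.get(item, {}).get(lv)
            for lv in administered
            if config.subitem_scores.get(item, {}).get(lv) is not None
        ]
        if scored:
            per_item_scores[item] = scored
    if config.aggregation == "sum_of_item_maxima":
        return sum(max(v) for v in per_item_scores.values())
    all_scores = [s for v in per_item_scores.values() for s in v]
    return max(all_scores, default=0)
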
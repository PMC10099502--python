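import numpy as np
import pandas as pd
import pytest

from outletchoice.choice import filter_estimable
from outletchoice.synthetic import (
    CHOICE_ATTRIBUTES,
    generate_choice_study,
    generate_study,
    kenya_like,
)

ATTRS = list(CHOICE_ATTRIBUTES)


@pytest.fixture(scope="session")
def small_study():
    """A small Kenya-like study with selection, linkage and choices."""
    return generate_study(kenya_like(n_respondents=300, seed=7), seed=7)


@pytest.fixture(scope="session")
def choice_study():
    """A choice-only study (every respondent chooses an outlet) with usable sets."""
    study = generate_choice_study(kenya_like(n_respondents=500, seed=11), seed=11)
    cs, _ = filter_estimable(study.choice_sets)
    return study, cs


def make_choice_sets(attr_values: dict, chosen: np.ndarray) -> pd.DataFrame:
    """Long choice-set table where every chooser faces the same alternatives.

    attr_values: attribute name -> per-alternative values (length n_alt);
    chosen: per-chooser index of the chosen alternative.
    """
    names = list(attr_values)
    n_alt = len(attr_values[names[0]])
    n = len(chosen)
    rid = np.repeat([f"R{i:05d}" for i in range(n)], n_alt)
    oid = np.tile([f"O{m:03d}" for m in range(n_alt)], n)
    df = pd.DataFrame({"respondent_id": rid, "outlet_id": oid})
    for name, vals in attr_values.items():
        df[name] = np.tile(np.asarray(vals, dtype=float), n)
    df["chosen"] = (np.tile(np.arange(n_alt), n) == np.repeat(chosen, n_alt)).astype(int)
    return df
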
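"""Packaged reference tables from the standard suspension tests.

Two small CSVs ship with the package:

* ``suspension_test_mbc.csv`` -- per-strain median bactericidal
  concentrations (%) of the five commercial disinfectants as determined by
  quantitative suspension tests (the standard-method side of the
  comparison).
* ``agreement_counts.csv`` -- per-disinfectant concordance counts between
  the label-free FCM calls and the standard tests: exact categorical
  agreement and agreement within one and two doubling dilutions, each as
  numerator/denominator over the 14 strains tested.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_suspension_mbc", "load_agreement_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_suspension_mbc() -> pd.DataFrame:
    """Standard-test MBC table (%), one row per strain, one column per agent."""
    return _read("suspension_test_mbc.csv").set_index("strain")


def load_agreement_counts() -> pd.DataFrame:
    """Per-disinfectant FCM-vs-standard concordance counts."""
    return _read("agreement_counts.csv").set_index("disinfectant")
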
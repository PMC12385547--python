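"""Bundled reference data.

``reference_summary.csv`` transcribes the published per-row summary
statistics (group means, SDs, confidence intervals, Bland-Altman
components, CVs and ICCs; n = 16) of a cervical spinal-cord DTI
test-retest / inter-scanner reproducibility study whose statistical battery
this package mirrors.  The raw per-participant data of that study are not
public; these printed summaries serve as worked-example inputs for
validating the report arithmetic (see ``cordti.pipeline.validate_tables``).

The ``scanner`` column holds the two scanner labels plus ``interscanner``
for the pooled cross-scanner comparison, where ``test``/``retest`` columns
carry the two scanners' pooled values and the pooled columns are empty.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_summary"]


def load_reference_summary() -> pd.DataFrame:
    """Published summary table as a DataFrame (one row per metric x region)."""
    with resources.files("cordti.data").joinpath("reference_summary.csv").open() as fh:
        return pd.read_csv(fh)
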
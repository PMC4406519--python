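"""Packaged example datasets."""

from __future__ import annotations

from importlib import resources

from .evidence import DoseResponseDataset


def load_hba1c_npdr() -> DoseResponseDataset:
    """The packaged 16-point HbA1c vs non-proliferative retinopathy table.

    Literature-derived dose-response points: HbA1c (%) against the risk of
    NPDR (percent, as cases per 100 patient-years, which is why one value
    exceeds 50). Its best-fitting pattern among the seven is linear.
    """
    path = resources.files("diabrisk").joinpath("data/hba1c_npdr.csv")
    with resources.as_file(path) as p:
        return DoseResponseDataset.from_csv(p, "hba1c", "npdr")
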
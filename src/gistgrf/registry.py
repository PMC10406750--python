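"""The 34-feature global radiomic feature (GRF) registry.

Each screening mammogram yields exactly 34 named features drawn from three
families: GLCM Haralick statistics (n=30), NGTDM coarseness (n=2) and the
first-order range (n=2). Every feature exists in two region variants:

* ``ROI_Std_*`` — the feature is computed per lattice block covering the
  breast and summarised as the standard deviation across blocks;
* ``SQ_*`` — the feature is computed once on the largest square inscribed
  in the breast mask.

GLCM features use pixel distance 3 for the lattice variant and 9 for the
inscribed square (the single exception is ``Sum_of_squares_variance``, whose
lattice variant also uses distance 9); NGTDM coarseness uses 3x3 and 9x9
neighbourhoods respectively.

The bundled CSV also carries the per-view predictor-importance profile and
univariate p-values reported by the screening reader study this pipeline
operationalises; those columns are reference inputs for worked examples and
are never used by the extraction code itself.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_registry", "feature_names", "FAMILIES"]

FAMILIES = ("GLCM", "NGTDM", "FOS")


@lru_cache(maxsize=1)
def load_registry() -> pd.DataFrame:
    """Return the registry table (34 rows, registry order).

    Columns: row, name, region (ROI/SQ), base (family-level feature name),
    family (GLCM/NGTDM/FOS), distance (GLCM pixel distance), window (NGTDM
    neighbourhood size), reported_p, cc_importance, mlo_importance.
    """
    with resources.files("gistgrf.data").joinpath("grf_registry.csv").open() as fh:
        reg = pd.read_csv(fh)
    reg["distance"] = reg["distance"].astype("Int64")
    reg["window"] = reg["window"].astype("Int64")
    if len(reg) != 34:
        raise RuntimeError("corrupt feature registry: expected 34 rows")
    return reg


def feature_names() -> list[str]:
    """The 34 feature names in registry order."""
    return load_registry()["name"].tolist()
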
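"""Shared helper: hand-assembled single-factor model fits for effect tests."""

import numpy as np
import pandas as pd

from pollidiv.mixed import MixedResult
from pollidiv.models import Design, F, ModelFit, ModelSpec


def make_lui_fit(beta_class, family="poisson", intercept=1.0, v=0.0):
    design = Design([F("LUI", "Primary_Minimal")])
    design.labels = ["(Intercept)", "LUI=Urban_Intense"]
    design.levels = {"LUI": ["Urban_Intense"]}
    beta = np.array([intercept, beta_class], float)
    result = MixedResult(
        beta=beta, vcov=np.eye(2) * v, loglik=0.0, aic=0.0, family=family,
        var_components={}, resid_var=1.0 if family == "gaussian" else None,
        ranef={}, group_names=("SS",), n_obs=10, n_params=2,
        fitted=np.zeros(10), residuals=np.zeros(10), converged=True)
    response = "richness" if family == "poisson" else "abundance_ln1p"
    return ModelFit(spec=ModelSpec(response, [F("LUI", "Primary_Minimal")]),
                    design=design, result=result, random=("SS",),
                    olre=False, data_index=pd.RangeIndex(10))
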
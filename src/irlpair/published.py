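"""Published immune-related lncRNA pair signatures usable as fixtures.

``SIX_PAIR_LUAD_SIGNATURE`` is a six-pair prognostic IRLP signature for
lung adenocarcinoma (TCGA-LUAD derived) with its multivariate Cox
coefficients; loading it as a :class:`~irlpair.model.SignatureModel`
allows risk-score arithmetic on external indicator data.
"""

from __future__ import annotations

import numpy as np

from .model import SignatureModel

SIX_PAIR_LUAD_SIGNATURE = {
    "AL590226.1|ITGB1-DT": -0.272620431506035,
    "ITGB1-DT|AC131971.1": 0.143614111251972,
    "ITGB1-DT|AL157838.1": 0.0193198554782944,
    "LINC00941|LINC02362": 0.189921097107668,
    "AC026369.3|HIF1A-AS3": -0.444557438396472,
    "ITGB1-DT|LINC00513": 0.119044206656088,
}


def six_pair_luad_model(cutoff: float = 0.0) -> SignatureModel:
    """The six-pair LUAD signature as a ready-to-score SignatureModel."""
    return SignatureModel(
        pairs=list(SIX_PAIR_LUAD_SIGNATURE),
        coefficients=np.array(list(SIX_PAIR_LUAD_SIGNATURE.values())),
        train_median_cutoff=cutoff,
    )
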
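"""Published benchmark values for the correlation-weight method.

These numbers come from a published ten-split study of Henry's law constant
(pHLC) models built with Monte Carlo-optimized SMILES correlation weights
on a 29,439-compound corpus.  The corpus itself is not publicly deposited,
but the printed per-attribute weights for one worked example, the split-1
model coefficients, the 10×10 cross-validation R² matrix and the per-model
active-attribute counts are reproduced here so that the package's
arithmetic (descriptor summation, row summaries, the Nac anti-correlation)
can be checked against published values without any download.
"""

from __future__ import annotations

import numpy as np

from .descriptor import CorrelationWeightTable, CWEntry
from .tokens import AttributeKey

__all__ = [
    "CYANAMIDE_SMILES",
    "CYANAMIDE_DCW",
    "cyanamide_weight_table",
    "SPLIT1_C0",
    "SPLIT1_C1",
    "SPLIT1_TRAIN_N",
    "SPLIT1_TRAIN_R2",
    "SPLIT1_TRAIN_F",
    "SCM_R2_MATRIX",
    "NAC_PER_MODEL",
]

#: Worked example: cyanamide, printed with DCW(3.15) = 3.6993 under the
#: split-1 model weights.
CYANAMIDE_SMILES = "NC#N"
CYANAMIDE_DCW = 3.6993

#: Split-1 weights covering cyanamide's seven attributes (two of the four
#: single-token attributes are the same N).
_CYANAMIDE_WEIGHTS = {
    AttributeKey.single("N"): 0.9532,
    AttributeKey.single("C"): -0.0412,
    AttributeKey.single("#"): 0.2896,
    AttributeKey.pair("N", "C"): 0.9275,
    AttributeKey.pair("C", "#"): 0.0088,
    AttributeKey.pair("N", "#"): 0.6083,
}


def cyanamide_weight_table() -> CorrelationWeightTable:
    """The published split-1 weights for cyanamide's attributes as a
    ready-to-use table (all entries active; counts unknown, set to 0)."""
    return CorrelationWeightTable(
        {k: CWEntry(weight=w, active=True, count=0) for k, w in _CYANAMIDE_WEIGHTS.items()}
    )


#: Published split-1 regression:  pHLC = 3.8465 (±0.0005) + 1.1055 (±0.0001) × DCW(3.15)
SPLIT1_C0 = 3.8465
SPLIT1_C1 = 1.1055

#: Published split-1 active-training row of the quality table.
SPLIT1_TRAIN_N = 7293
SPLIT1_TRAIN_R2 = 0.8089
SPLIT1_TRAIN_F = 30855

#: Published 10×10 determination-coefficient matrix of the self-consistent
#: model system: row i = model M(i+1), column k = split S(k+1).
SCM_R2_MATRIX = np.array(
    [
        [0.8046, 0.8191, 0.8045, 0.7898, 0.7918, 0.8105, 0.8072, 0.7958, 0.7984, 0.7873],
        [0.8280, 0.8239, 0.8132, 0.8040, 0.8221, 0.8283, 0.8147, 0.8265, 0.8222, 0.8271],
        [0.8098, 0.8048, 0.8157, 0.7895, 0.8161, 0.8194, 0.8175, 0.8107, 0.8233, 0.8206],
        [0.7970, 0.7901, 0.7844, 0.8002, 0.8020, 0.8065, 0.8035, 0.7924, 0.8149, 0.8146],
        [0.8093, 0.8226, 0.8278, 0.8099, 0.8239, 0.8233, 0.8353, 0.8180, 0.8116, 0.8406],
        [0.8196, 0.8227, 0.8216, 0.8083, 0.8197, 0.8240, 0.8121, 0.8184, 0.8400, 0.8204],
        [0.7986, 0.7932, 0.8078, 0.7931, 0.8154, 0.7982, 0.8030, 0.7861, 0.8147, 0.8166],
        [0.8125, 0.8227, 0.8193, 0.7985, 0.8179, 0.8240, 0.8106, 0.8132, 0.8268, 0.8282],
        [0.7881, 0.7970, 0.8100, 0.8003, 0.7933, 0.8262, 0.8110, 0.8100, 0.8067, 0.8177],
        [0.7789, 0.8005, 0.8043, 0.8059, 0.8241, 0.8053, 0.8162, 0.8083, 0.8202, 0.8073],
    ]
)

#: Published number of active attributes (optimized parameters) per model.
NAC_PER_MODEL = np.array([100, 97, 96, 96, 95, 98, 98, 97, 100, 103])
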
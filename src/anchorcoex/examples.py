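"""Published worked-example data: TPM profiles of the barley Btr-like genes.

The motivating study profiled the brittle-rachis-related *Btr1-like* and
*Btr2-like* gene copies across a 212-library barley compendium and
reported their replicate-averaged TPM values in the anther and meiocyte
during the early stages of meiosis, plus an outlier root sample pair
from a heat-stress experiment.  The two highest-expressed copies are
reproduced here as a small ready-made compendium for demonstrations and
cross-checks: both genes peak in the meiocyte at pachytene-diplotene
(244.05 and 112.70 TPM) and correlate at Pearson r = 0.99.
"""

from __future__ import annotations

import pandas as pd

from .io import ExpressionCompendium, SampleMeta

BTR_SAMPLE_IDS = (
    "anther.pre-meiosis",
    "anther.leptotene-zygotene",
    "anther.pachytene-diplotene",
    "anther.metaphase-tetrad",
    "meiocyte.leptotene-zygotene",
    "meiocyte.pachytene-diplotene",
    "root.22C",
    "root.35C",
)

#: Replicate-averaged TPM across the eight samples above.
BTR_MEIOSIS_TPM = {
    "Btr1-like-a": (11.87, 40.75, 145.34, 115.23, 83.01, 244.05, 4.58, 7.15),
    "Btr2-like-a": (0.0, 7.20, 63.61, 57.40, 24.55, 112.70, 0.0, 0.08),
}

#: Sample where both genes peak.
BTR_PEAK_SAMPLE = "meiocyte.pachytene-diplotene"


def btr_meiosis_compendium() -> ExpressionCompendium:
    """The two Btr-like anchor profiles as a 2 x 8 compendium."""
    samples = []
    for sid in BTR_SAMPLE_IDS:
        tissue, stage = sid.split(".", 1)
        project = "heat-stress" if tissue == "root" else "meiosis"
        samples.append(SampleMeta(sid, project, tissue, stage, sid))
    values = pd.DataFrame(
        {sid: [BTR_MEIOSIS_TPM[g][i] for g in BTR_MEIOSIS_TPM]
         for i, sid in enumerate(BTR_SAMPLE_IDS)},
        index=list(BTR_MEIOSIS_TPM),
    )
    return ExpressionCompendium(values=values, samples=samples)
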
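"""accessprobe: antisense probe panel design and in vivo RNA accessibility mapping.

A toolkit around a transcription anti-termination reporter for regional RNA
accessibility: biophysical hybridization scoring and knowledge-gradient
weighted set-cover probe selection (:mod:`accessprobe.design`,
:mod:`accessprobe.thermo`), paired-read transcript-length quantification
(:mod:`accessprobe.readproc`), relative-accessibility calculation
(:mod:`accessprobe.accessibility`), chaperone-dependency statistics
(:mod:`accessprobe.stats`), functional-region calling and prediction
filtering (:mod:`accessprobe.funcmap`), and a ground-truth synthetic data
generator (:mod:`accessprobe.simdata`).
"""

from importlib.resources import files as _files

import pandas as _pd

from . import accessibility, design, funcmap, readproc, simdata, stats, thermo  # noqa: F401

__version__ = "0.1.0"


def load_emsa_benchmark() -> "_pd.DataFrame":
    """Bundled in vitro (EMSA) validation benchmark for three sRNAs.

    Columns: srna, mrna, rank (of 100), category (INTERFACE / Top-ranked /
    Both) and binding (yes / weak / no).
    """
    return _pd.read_csv(_files("accessprobe.data") / "emsa_benchmark.csv")
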
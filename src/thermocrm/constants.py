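"""Physical constants and global model bounds."""

import numpy as np
from scipy.constants import Avogadro as N_AVOGADRO
from scipy.constants import R as GAS_CONSTANT

#: Minimum ATP transduced per reaction event.  One third of an ATP is roughly
#: the free energy of pumping a single ion across the membrane, the smallest
#: useful quantum of energy conservation available to a cell.
ETA_MIN = 1.0 / 3.0

#: Generations needed for a population to grow 100-fold; sets the ribosome
#: reallocation timescale tau_g = LOG2_100 / lambda.
LOG2_100 = float(np.log2(100.0))

#: ATP-pool scale (molecules per cell) over which reverse reaction flux is
#: smoothly gated off as the pool empties; reverse catalysis spends ATP, so
#: its rate must vanish continuously at a = 0.  ~0.03% of the ATP cost of
#: synthesising one cell mass.
ATP_GATE = 1.0e6

__all__ = ["GAS_CONSTANT", "N_AVOGADRO", "ETA_MIN", "LOG2_100", "ATP_GATE"]
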
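"""Bundled gene signatures.

The erythroid progenitor-like and prostate epithelial signatures are the
eight-gene marker panels used to separate EpCAM+ bone-marrow contaminants
from genuine prostate disseminated tumor cells; NKX3-1 is the single most
discriminative prostate marker.

The default dormancy signature shipped here is SYNTHETIC: the p38-linked
dormancy gene lists (26 up, 21 down, including seven genes that were never
published) are not redistributable from this package, so placeholder
symbols (DORMUP_SYN*, DORMDN_SYN*) are bundled purely so that the coverage
statistic and the synthetic-data generator have a concrete, size-matched
signature to operate on. Supply real GMT files for any analysis of real
data; the coverage statistic is signature-agnostic.
"""

from __future__ import annotations

from .io import Direction, GeneSet

ERYTHROID_GENES = ("AHSP", "CA1", "HBA1", "HBA2", "HBB", "HBD", "LMO2", "MYB")
PROSTATE_GENES = ("AR", "CD63", "FOLH1", "HOXB13", "ID1", "NKX3-1", "RELB", "XAGE1A")
NKX31 = "NKX3-1"

N_DORMANCY_UP = 26   # 19 published + 7 unpublished quiescence genes
N_DORMANCY_DOWN = 21

DORMANCY_UP_GENES = tuple(f"DORMUP_SYN{i:02d}" for i in range(1, N_DORMANCY_UP + 1))
DORMANCY_DOWN_GENES = tuple(f"DORMDN_SYN{i:02d}" for i in range(1, N_DORMANCY_DOWN + 1))


def erythroid_signature() -> GeneSet:
    return GeneSet("ERYTHROID_PROGENITOR", frozenset(ERYTHROID_GENES), Direction.UNSIGNED)


def prostate_signature() -> GeneSet:
    return GeneSet("PROSTATE_EPITHELIAL", frozenset(PROSTATE_GENES), Direction.UNSIGNED)


def dormancy_up_signature() -> GeneSet:
    """Synthetic stand-in for the 26-gene dormancy UP signature."""
    return GeneSet("DORMANCY_SYN_UP", frozenset(DORMANCY_UP_GENES), Direction.UP)


def dormancy_down_signature() -> GeneSet:
    """Synthetic stand-in for the 21-gene dormancy DOWN signature."""
    return GeneSet("DORMANCY_SYN_DOWN", frozenset(DORMANCY_DOWN_GENES), Direction.DOWN)
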
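"""Packaged reference data: experimentally characterized TFR/neighbor pairs.

The panel covers nine divergent regulator-neighbor pairs from
*S. coelicolor* and *S. griseus* (ActR, SGR3979, SCO3367, SGR5269, SGR3402,
SCO4099, SCO7222, SGR6912 and AtrA) whose regulatory relationships were
settled by gel-shift, footprinting and luciferase-reporter experiments,
together with the operator sequences footprinted for seven of them. These
serve both as a worked demonstration of the distance rule and as regression
fixtures for the palindrome scanner.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .context import ContextCall, Group, SeparationResult

#: Operator consensus of the three SCO7222 sites (monooxygenase regulator).
SCO7222_CONSENSUS = "TGGAACGNCGTTCCA"

#: Regulators in the panel experimentally shown to repress their divergent
#: neighbor; all lie within 200 bp of it.
REPRESSED_PANEL = frozenset({"SCO5082", "SGR3979", "SCO3367", "SCO4099", "SCO7222"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("tfrctx.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_pairs() -> pd.DataFrame:
    """The nine-pair panel: loci, products, separations, observed regulation."""
    return _read("reference_pairs.tsv")


def load_operator_sites() -> dict[str, list[str]]:
    """Footprinted operator sequences keyed by regulator name."""
    df = _read("operator_sites.tsv")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.tfr, []).append(row.sequence)
    return out


def reference_context_calls() -> list[ContextCall]:
    """The panel rendered as DIVERGENT context calls, ready for target
    prediction (the panel's separations are all from published coordinates,
    so left/right placement within the pair is immaterial here)."""
    calls = []
    for row in load_reference_pairs().itertuples(index=False):
        sep = int(row.separation_bp)
        calls.append(
            ContextCall(
                tfr_locus=row.tfr_locus,
                replicon_id="reference",
                group=Group.DIVERGENT,
                divergent_neighbor=row.target_locus,
                separation=SeparationResult(sep, sep, row.target_locus, row.tfr_locus),
            )
        )
    return calls
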
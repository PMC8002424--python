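"""Published ten-compound benchmark: in-vitro calls vs model calls.

Ships as a packaged fixture (``data/invitro_mie_comparison.csv``) holding,
for five biocides per endpoint, the experimental in-vitro call, the
structure-based prediction (molecular dynamics for PPAR-γ inactivation,
pharmacophore mapping for TLR4 activation) and the QSAR prediction. These
are reported observations, not quantities this package computes; the
package recomputes the per-method agreement rates from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import Endpoint
from .metrics import compare_with_experiment

_FIXTURE = "invitro_mie_comparison.csv"
_METHODS = ("structure_based", "qsar")


def load_invitro_comparison() -> pd.DataFrame:
    """The packaged ten-compound comparison table."""
    with resources.files("mieqsar.data").joinpath(_FIXTURE).open() as fh:
        return pd.read_csv(fh)


def _calls(frame: pd.DataFrame, column: str) -> dict[str, int]:
    return {cas: int(v == "Positive")
            for cas, v in zip(frame["cas"], frame[column])}


def benchmark_accuracies(frame: pd.DataFrame | None = None) -> dict:
    """Agreement of each modeling method with the in-vitro calls.

    Returns ``{endpoint: {method: accuracy}}`` for the two endpoints and
    the two methods (structure-based and QSAR), computed with
    :func:`mieqsar.metrics.compare_with_experiment`.
    """
    frame = frame if frame is not None else load_invitro_comparison()
    out: dict[str, dict[str, float]] = {}
    for endpoint in (Endpoint.PPARG_INACTIVATION, Endpoint.TLR4_ACTIVATION):
        block = frame[frame["endpoint"] == endpoint.value]
        experimental = _calls(block, "in_vitro")
        out[endpoint.value] = {}
        for method in _METHODS:
            acc, _ = compare_with_experiment(_calls(block, method),
                                             experimental)
            out[endpoint.value][method] = acc
    return out
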
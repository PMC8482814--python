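"""Community-wide functional projection of taxon tables through trait matrices.

The pathway abundance of a sample is the taxon-abundance-weighted sum of
gene/pathway copy numbers over the community::

    pathway[sample, p] = sum_t count[sample, t] * copies[t, p]

This captures only the abundance-weighting step of community-wide function
prediction; placement, hidden-state inference and pathway-coverage logic of
the full prediction stack are intentionally out of scope.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .io import FeatureTable, TraitMatrix

__all__ = ["project_traits"]


def project_traits(table: FeatureTable, traits: TraitMatrix) -> FeatureTable:
    """Project a taxon table to a pathway table via copy numbers.

    Taxa absent from the trait matrix are dropped with a warning reporting
    the fraction of total abundance lost.  The projection is linear in the
    input counts.
    """
    present = [f for f in table.feature_ids if f in traits.data.index]
    missing = [f for f in table.feature_ids if f not in traits.data.index]
    if not present:
        raise ValueError("no table feature is covered by the trait matrix")
    if missing:
        total = table.data.to_numpy().sum()
        dropped = table.data[missing].to_numpy().sum()
        frac = dropped / total if total > 0 else 0.0
        warnings.warn(
            f"{len(missing)} feature(s) absent from the trait matrix dropped "
            f"({frac:.1%} of total abundance)",
            stacklevel=2,
        )
    copies = traits.data.loc[present]
    projected = table.data[present].to_numpy(dtype=float) @ copies.to_numpy(dtype=float)
    data = pd.DataFrame(projected, index=table.sample_ids, columns=traits.pathway_ids)
    return FeatureTable(data=data, feature_kind="pathway")
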
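"""Synthetic qPCR Ct tables with known group effects.

Each sample gets a housekeeping Ct around a baseline cycle number and a
target-gene Ct offset by a base ΔCt plus a group-specific shift;
independent Gaussian noise perturbs both genes.  A shift of +1 cycle in
a group therefore yields a true fold change of 0.5 relative to an
unshifted reference group (fold = 2^-ΔΔCt).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..expression import CtRecord

__all__ = ["make_ct_table"]


def make_ct_table(
    n_per_group: int,
    group_effects: Mapping[str, float],
    seed: int = 0,
    target_gene: str = "Gria2",
    housekeeping_gene: str = "Gapdh",
    housekeeping_mean_ct: float = 18.0,
    base_delta_ct: float = 5.0,
    between_sample_sd: float = 0.4,
    noise_sd: float = 0.15,
    hemisphere: str = "ipsi",
) -> list[CtRecord]:
    """Generate seeded Ct records for target + housekeeping genes.

    Parameters
    ----------
    n_per_group : int
        Samples per group, >= 1.
    group_effects : mapping of group name -> ΔCt shift (cycles)
        A positive shift lowers expression (fold 2^-shift vs a
        zero-shift group).
    between_sample_sd : float
        SD of the per-sample loading offset applied to both genes (a
        fold-neutral nuisance, cancelled by ΔCt).
    noise_sd : float
        SD of the independent per-well technical noise (cycles).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for group in group_effects:
        shift = float(group_effects[group])
        for i in range(n_per_group):
            sample = f"{group}_{i + 1:02d}"
            loading = rng.normal(0.0, between_sample_sd) if between_sample_sd > 0 else 0.0
            hk = housekeeping_mean_ct + loading + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            tg = (
                housekeeping_mean_ct
                + loading
                + base_delta_ct
                + shift
                + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            )
            records.append(CtRecord(sample, group, housekeeping_gene, float(hk), hemisphere))
            records.append(CtRecord(sample, group, target_gene, float(tg), hemisphere))
    return records
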
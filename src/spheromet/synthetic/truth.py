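"""Ground-truth container stored losslessly alongside generated images."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GroundTruth:
    """Known truth for a generated dataset; only relevant fields are set.

    Attributes
    ----------
    true_positions : (frames, n_cells, 3) array or None
        Per-frame (z, y, x) nucleus centers, px.
    true_identities : array of int or None
        Cell ids, one per column of ``true_positions``.
    true_circularity : (frames,) array or None
        Programmed analytic circularity per frame.
    true_tj_length : float or None
        Programmed total junction-network edge length, px.
    true_pa_lengths : array or None
        Programmed PA major-axis lengths, px.
    true_contact_length : (frames,) array or None
        Programmed fusion-neck (contact) width per frame, px.
    true_doublet_length : (frames,) array or None
        Programmed doublet long-axis length per frame, px.
    params : dict
        Generator parameters, including the seed.
    """

    true_positions: np.ndarray | None = None
    true_identities: np.ndarray | None = None
    true_circularity: np.ndarray | None = None
    true_tj_length: float | None = None
    true_pa_lengths: np.ndarray | None = None
    true_contact_length: np.ndarray | None = None
    true_doublet_length: np.ndarray | None = None
    true_cell_count: int | None = None
    params: dict = field(default_factory=dict)

    def positions_frame(self) -> pd.DataFrame | None:
        """Long-format (frame, id, z, y, x) table of true positions."""
        if self.true_positions is None:
            return None
        f, n, _ = self.true_positions.shape
        ids = self.true_identities if self.true_identities is not None else np.arange(n)
        return pd.DataFrame({
            "frame": np.repeat(np.arange(f), n),
            "id": np.tile(ids, f),
            "z": self.true_positions[:, :, 0].ravel(),
            "y": self.true_positions[:, :, 1].ravel(),
            "x": self.true_positions[:, :, 2].ravel(),
        })
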
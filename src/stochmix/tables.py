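"""Cell-table conventions.

A *cell table* is a plain :class:`pandas.DataFrame` with one row per cell
(or cytometry event).  A handful of column names are reserved for metadata;
every other numeric column is treated as a channel (drug tag, auxiliary dye,
phenotype reporter, latent uptake, ...).

Reserved columns:

``cell_id``      integer identifier, unique within a table
``x_um, y_um``   position in micrometres
``sample``       sample label (string)
``time_h``       harvest time in hours
``compartment``  ``"attached"`` or ``"detached"`` (cytometry death readout)
"""

from __future__ import annotations

import pandas as pd

#: Columns that are never interpreted as channels.
RESERVED_COLUMNS = ("cell_id", "x_um", "y_um", "sample", "time_h", "compartment")

#: Canonical column order for event CSV files: metadata first, channels after
#: position, labels at the end.
CSV_LEADING = ("cell_id", "x_um", "y_um")
CSV_TRAILING = ("sample", "time_h", "compartment")


def channel_columns(cells: pd.DataFrame) -> list[str]:
    """Names of all channel columns in table order."""
    return [c for c in cells.columns if c not in RESERVED_COLUMNS]


def ordered_columns(cells: pd.DataFrame) -> list[str]:
    """Documented CSV column order: cell_id, x_um, y_um, channels..., labels."""
    cols = [c for c in CSV_LEADING if c in cells.columns]
    cols += channel_columns(cells)
    cols += [c for c in CSV_TRAILING if c in cells.columns]
    return cols
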
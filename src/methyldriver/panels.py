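"""Published minimal colorectal-cancer methylation panel.

The four-cluster, five-probe panel (ADHFE1-Cluster1, CNRIP1-Cluster1, MAFB,
TNS4) reported for separating colorectal cancer from normal tissue.  Kept as
a package constant so the probe -> cluster bookkeeping can be exercised and
so real Illumina-array exports restricted to these probes can be aggregated
directly.
"""

from __future__ import annotations

import pandas as pd

from .core_io import ClusterDefinition

#: (probe_id, cluster_id, gene symbol) rows of the published panel
CRC_PANEL_PROBES: tuple[tuple[str, str, str], ...] = (
    ("cg01988129", "ADHFE1-Cluster1", "ADHFE1"),
    ("cg08090772", "ADHFE1-Cluster1", "ADHFE1"),
    ("cg07080358", "CNRIP1-Cluster1", "CNRIP1"),
    ("cg02497758", "MAFB", "MAFB"),
    ("cg08696192", "TNS4", "TNS4"),
)


def panel_probe_table() -> pd.DataFrame:
    """The panel as a probe-level table (probe_id, cluster_id, gene)."""
    return pd.DataFrame(CRC_PANEL_PROBES, columns=["probe_id", "cluster_id", "gene"])


def panel_cluster_definitions() -> list[ClusterDefinition]:
    """Cluster definitions grouping the panel probes by their cluster label."""
    table = panel_probe_table()
    defs = []
    for cluster_id in dict.fromkeys(table["cluster_id"]):
        sub = table[table["cluster_id"] == cluster_id]
        defs.append(
            ClusterDefinition(
                cluster_id=cluster_id,
                gene=sub["gene"].iloc[0],
                probe_ids=tuple(sub["probe_id"]),
            )
        )
    return defs
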
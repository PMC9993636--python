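#!/usr/bin/env python
"""Categorical classification and the median-joining network of CIVD factors.

Thresholds each subject's phase-2 eNO-independent and neurogenic amplitudes
against the non-CIVD group means, labels the typical-CIVD / typical-NonCIVD
profiles, and writes the median-joining network over the 3-bit profiles.
"""

import sys
from pathlib import Path

import networkx as nx
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from civdwave import io  # noqa: E402
from civdwave.network import (  # noqa: E402
    classify_subjects,
    label_typical_groups,
    median_joining,
    network_summary,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    phen = pd.read_csv(ROOT / "phenotypes.tsv", sep="\t", na_values=io.NA)
    cls = classify_subjects(phen)
    cls.profiles["group"] = label_typical_groups(cls.profiles)
    counts = cls.profiles["group"].value_counts()
    print("classification thresholds (non-CIVD means):",
          {k: round(v, 3) for k, v in cls.thresholds.items()})
    print("groups:", counts.to_dict())
    hi_eno = int(cls.profiles["eno_independent_high"].sum())
    hi_neuro = int(cls.profiles["neurogenic_high"].sum())
    n = len(cls.profiles)
    print(f"eNO-independent: {n - hi_eno} low / {hi_eno} high; "
          f"neurogenic: {n - hi_neuro} low / {hi_neuro} high")

    net = median_joining(cls.profiles)
    summ = network_summary(net)
    print(f"median-joining network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges")
    print(summ.to_string(index=False))

    cls.profiles.drop(columns=["profile"]).to_csv(
        ROOT / "profiles.tsv", sep="\t", index=False)
    summ.to_csv(ROOT / "network_nodes.tsv", sep="\t", index=False)
    g2 = nx.relabel_nodes(net, {v: "".join(map(str, v)) for v in net.nodes})
    nx.write_graphml(g2, ROOT / "network.graphml")


if __name__ == "__main__":
    main()
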
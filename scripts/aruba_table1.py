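#!/usr/bin/env python
"""Optional check against the real CASAS Aruba dataset (download required).

Parses a locally downloaded Aruba ``data`` file, assigns labels from the
begin/end annotations, and prints the per-activity event counts for
comparison with the dataset's published statistics (e.g. 288,407
Meal_Preparation events).  The dataset is available from
http://casas.wsu.edu/datasets/ and is NOT shipped with this package.

Usage::

    python scripts/aruba_table1.py /path/to/aruba/data
"""

from __future__ import annotations

import argparse
from collections import Counter

from stigsense import assign_labels, read_casas
from stigsense.aruba import activity_catalog, sensor_catalog


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("data", help="Path to the Aruba 'data' file")
    args = parser.parse_args()

    stream = read_casas(args.data, (sensor_catalog(), activity_catalog()))
    labeled = assign_labels(stream)
    counts = Counter(e.label for e in labeled.events)
    total = len(labeled)
    print(f"{'activity':<22} {'events':>10} {'proportion':>12}")
    for idx in sorted(counts):
        name = labeled.activity_catalog.name(idx)
        print(f"{name:<22} {counts[idx]:>10} {counts[idx] / total:>11.4%}")
    print(f"{'total':<22} {total:>10}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
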
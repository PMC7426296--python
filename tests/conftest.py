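import numpy as np
import pandas as pd
import pytest

from metabomix.chemmass import CompoundDatabase
from metabomix.ident import Candidate, MatchResult
from metabomix.peaktable import PeakTable


@pytest.fixture
def tiny_db() -> CompoundDatabase:
    """Four compounds, two of which are isomers (identical formula/mass)."""
    return CompoundDatabase.from_frame(
        pd.DataFrame(
            {
                "compound_id": ["C1", "C2", "C3", "C4"],
                "name": ["glutaric acid", "heavier", "isomer-a", "isomer-b"],
                "formula": ["C5H8O4", "C6H12O6", "C4H8O2", "C4H8O2"],
                "class_label": ["others", "lipids", "others", "others"],
                "is_standard": [False, False, False, False],
            }
        )
    )


@pytest.fixture
def design_frame() -> pd.DataFrame:
    """Two genotypes x two biological x two technical replicates."""
    rows = []
    for genotype in ("WT", "KO"):
        for b in (1, 2):
            for t in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{genotype}_b{b}_t{t}",
                        "genotype": genotype,
                        "treatment": "none",
                        "biological_replicate": f"{genotype}_b{b}",
                        "technical_replicate": f"t{t}",
                        "organ": "kidney",
                    }
                )
    return pd.DataFrame(rows)


def make_peak_table(mz, rt, height, areas, samples, polarity="positive"):
    n = len(mz)
    index = pd.Index([f"P{i}" for i in range(n)], name="peak_id")
    meta = pd.DataFrame(
        {"mz": mz, "rt": rt, "polarity": polarity, "height": height}, index=index
    )
    area_frame = pd.DataFrame(np.asarray(areas, dtype=float), index=index, columns=samples)
    return PeakTable(meta, area_frame)


def matches_from_errors(best_errors, second_errors):
    """Build minimal MatchResults carrying given best/second ppm errors."""
    out = []
    for i, (eb, es) in enumerate(zip(best_errors, second_errors)):
        assert abs(eb) <= abs(es)
        best = Candidate((f"C{i}",), f"F{i}", "[M+H]+", float(eb), 100.0, 100.0)
        second = Candidate((f"D{i}",), f"G{i}", "[M+H]+", float(es), 100.0, 100.0)
        out.append(MatchResult(f"P{i}", best, second))
    return out
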
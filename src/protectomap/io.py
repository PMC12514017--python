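"""TSV interchange with provenance headers.

Every table the pipeline writes starts with comment lines recording the
stage, the global seed, and a hash of the run configuration, so any
intermediate can be traced back to the run that produced it. Readers skip
those lines transparently.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, stage: str = "", seed: int | None = None,
              cfg_hash: str = "", index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a participants/regions x columns matrix with integer region ids."""
    df = read_tsv(path)
    try:
        df.columns = df.columns.astype(int)
    except (TypeError, ValueError):
        pass
    return df
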
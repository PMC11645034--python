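"""Readers and writers for raw signals and datasets.

Formats: CSV (channels as columns, one ``# fs=<Hz>`` header line or a
sidecar), NPZ (arrays + JSON metadata), and optionally EDF via mne.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import LabeledDataset, RawEEG, ValidationError


class FormatError(ValueError):
    pass


def write_signals_csv(path, x: RawEEG) -> None:
    """One trial per file: channels as columns, ``# fs=<Hz>`` header comment."""
    import pandas as pd

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={x.fs}\n")
        pd.DataFrame(x.data.T, columns=x.ch_names).to_csv(fh, index=False)


def read_signals_csv(path) -> RawEEG:
    import pandas as pd

    path = Path(path)
    fs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1].strip())
            df = pd.read_csv(fh)
        else:
            raise FormatError(f"{path}: missing '# fs=<Hz>' header line")
    data = df.to_numpy(dtype=np.float64).T
    bad = [c for c, row in zip(df.columns, data) if not np.all(np.isfinite(row))]
    if bad:
        raise ValidationError(f"{path}: non-finite values in channels {bad}")
    return RawEEG(data=data, fs=fs, ch_names=[str(c) for c in df.columns])


def write_signals_npz(path, x: RawEEG) -> None:
    np.savez(path, data=x.data, fs=np.float64(x.fs), ch_names=np.array(x.ch_names))


def read_signals_npz(path) -> RawEEG:
    with np.load(path, allow_pickle=False) as z:
        if "fs" not in z:
            raise FormatError(f"{path}: missing sampling rate entry 'fs'")
        return RawEEG(data=z["data"], fs=float(z["fs"]), ch_names=[str(c) for c in z["ch_names"]])


def read_signals_edf(path) -> RawEEG:
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise FormatError("EDF support requires the optional 'mne' dependency") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawEEG(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), ch_names=list(raw.ch_names))


_READERS = {"csv": read_signals_csv, "npz": read_signals_npz, "edf": read_signals_edf}


def read_signals(path, fmt: str | None = None) -> RawEEG:
    """Dispatch on ``fmt`` or the file extension."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in _READERS:
        raise FormatError(f"unknown signal format {fmt!r} (supported: {sorted(_READERS)})")
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[fmt](path)


def write_dataset_npz(path, ds: LabeledDataset) -> None:
    """All trials + ratings + JSON metadata in one NPZ (equal-length trials)."""
    arrays = {f"trial{i}": t.data for i, t in enumerate(ds.trials)}
    np.savez(
        path,
        ratings=ds.ratings,
        fs=np.float64(ds.trials[0].fs),
        meta=json.dumps({**ds.metadata, "scheme": ds.scheme, "n_trials": ds.n_trials}),
        **arrays,
    )


def read_dataset_npz(path) -> LabeledDataset:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        fs = float(z["fs"])
        trials = [RawEEG(data=z[f"trial{i}"], fs=fs) for i in range(int(meta["n_trials"]))]
        return LabeledDataset(trials=trials, ratings=z["ratings"], scheme=meta["scheme"], metadata=meta)


def write_dataset_csv(outdir, ds: LabeledDataset) -> None:
    """One CSV per trial plus a ratings.csv and metadata.json."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(ds.trials):
        write_signals_csv(outdir / f"trial{i:04d}.csv", t)
    ratings = np.atleast_2d(ds.ratings.T).T
    cols = ["class"] if ds.scheme == "four-class" else ["V", "A", "D"]
    pd.DataFrame(ratings, columns=cols).to_csv(outdir / "ratings.csv", index=False)
    (outdir / "metadata.json").write_text(json.dumps({**ds.metadata, "scheme": ds.scheme}, sort_keys=True))


def read_dataset_csv(indir) -> LabeledDataset:
    import pandas as pd

    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    trials = [read_signals_csv(p) for p in sorted(indir.glob("trial*.csv"))]
    ratings_df = pd.read_csv(indir / "ratings.csv")
    ratings = ratings_df.to_numpy()
    if meta["scheme"] == "four-class":
        ratings = ratings[:, 0].astype(np.int64)
    return LabeledDataset(trials=trials, ratings=ratings, scheme=meta["scheme"], metadata=meta)
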
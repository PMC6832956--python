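"""On-disk formats.

Spectra travel as delimited text: first column the wavenumber axis, one
column per spectrum, header row of spectrum ids.  The labels manifest is a
delimited table with columns id, species, genus, family, growth_habit.
Images are 8-bit grayscale TIFF or PNG.  Delimiters are auto-detected among
comma, tab and semicolon.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .spectrum import MANIFEST_COLUMNS, SpectralDataset

_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def write_spectra_table(path: str | Path, dataset: SpectralDataset, delimiter: str = ",") -> None:
    path = Path(path)
    ids = dataset.manifest["id"].tolist()
    table = pd.DataFrame(dataset.intensities.T, columns=ids)
    table.insert(0, "wavenumber_cm1", dataset.axis)
    table.to_csv(path, sep=delimiter, index=False)


def write_manifest(path: str | Path, dataset: SpectralDataset, delimiter: str = ",") -> None:
    dataset.manifest.to_csv(Path(path), sep=delimiter, index=False)


def read_spectral_dataset(spectra_path: str | Path, manifest_path: str | Path) -> SpectralDataset:
    """Load a spectra table + manifest pair, validating the schema."""
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    table = pd.read_csv(spectra_path, sep=_sniff_delimiter(spectra_path))
    if table.shape[1] < 2:
        raise SchemaError("spectra table needs a wavenumber column plus spectra")
    axis = table.iloc[:, 0].to_numpy(dtype=float)
    matrix = table.iloc[:, 1:].to_numpy(dtype=float).T
    ids = list(table.columns[1:])

    manifest = pd.read_csv(manifest_path, sep=_sniff_delimiter(manifest_path))
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest is missing required column(s): {', '.join(missing)}")
    manifest = manifest.astype({c: str for c in MANIFEST_COLUMNS})
    order = {sid: i for i, sid in enumerate(manifest["id"])}
    unknown = [sid for sid in ids if sid not in order]
    if unknown:
        raise SchemaError(f"spectra columns missing from the manifest: {unknown[:3]}...")
    manifest = manifest.set_index("id").loc[ids].reset_index()
    return SpectralDataset(axis, matrix, manifest)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
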
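"""On-disk cohort layout: NIfTI stacks, sidecar tables, manifest TSV."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .images import write_image, write_labels, read_image, read_labels
from .phantom import Bundle, RoiLabelScheme
from .protocols import DwiProtocol, QmtProtocol, ZspecProtocol

MANIFEST_COLUMNS = ("subject", "segment", "condition", "dwi", "qmt", "zspec",
                    "labels", "seed")


def write_cohort(bundles: dict, out_dir, dwi_protocol: DwiProtocol,
                 qmt_protocol: QmtProtocol, zspec_protocol: ZspecProtocol,
                 seed: int) -> Path:
    """Write every bundle plus shared sidecars; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dwi_protocol.write_bval_bvec(out / "dwi.bval", out / "dwi.bvec")
    qmt_protocol.to_table().to_csv(out / "qmt_protocol.tsv", sep="\t", index=False)
    zspec_protocol.to_table().to_csv(out / "zspec_offsets.tsv", sep="\t", index=False)

    rows = []
    labels_path = None
    for key in sorted(bundles):
        b: Bundle = bundles[key]
        stem = f"sub-{b.subject:02d}_seg-{b.segment}_{b.condition}"
        if labels_path is None:
            labels_path = out / "labels.nii.gz"
            write_labels(b.labels, labels_path)
            (out / "labels.json").write_text(
                json.dumps(b.scheme.to_json_dict(), indent=2))
        paths = {}
        for mod in ("dwi", "qmt", "zspec"):
            p = out / f"{stem}_{mod}.nii.gz"
            write_image(getattr(b, mod), p)
            paths[mod] = p.name
        (out / f"{stem}_truth.json").write_text(json.dumps(
            {f"{n}/{s}": v for (n, s), v in b.truth.items()}, indent=2))
        rows.append({"subject": b.subject, "segment": b.segment,
                     "condition": b.condition, **paths,
                     "labels": labels_path.name, "seed": seed})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def read_scheme(path) -> RoiLabelScheme:
    data = json.loads(Path(path).read_text())
    return RoiLabelScheme({int(c): (v["name"], v["side"]) for c, v in data.items()})


def read_manifest(manifest_path) -> tuple[pd.DataFrame, Path]:
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return table, manifest_path.parent


def load_bundle(row: pd.Series, root: Path, scheme: RoiLabelScheme) -> Bundle:
    return Bundle(
        subject=int(row["subject"]), segment=int(row["segment"]),
        condition=str(row["condition"]),
        dwi=read_image(root / row["dwi"]),
        qmt=read_image(root / row["qmt"]),
        zspec=read_image(root / row["zspec"]),
        labels=read_labels(root / row["labels"])[..., 0],
        scheme=scheme, truth={},
    )
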
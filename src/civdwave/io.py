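"""Readers/writers for the pipeline's on-disk formats.

Recordings travel as per-subject TSV (time_s, flow_au, temp_c) plus a
cohort manifest TSV; genotypes as minimal VCF 4.2 (GT only, read back via
cyvcf2) or a dosage TSV; the truth ledger and run configuration as JSON.
All tables are tab-separated UTF-8 with missing values written as NA.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sigproc import Recording

NA = "NA"


def _atomic_write(path: Path, text: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_recordings(recordings, out_dir) -> Path:
    """One TSV per subject plus manifest.tsv; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.tsv"
        df = pd.DataFrame(
            {"time_s": rec.times_s, "flow_au": rec.flow, "temp_c": rec.temp}
        )
        df.to_csv(out / fname, sep="\t", index=False, na_rep=NA)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "file": fname,
                "immersion_start_s": rec.immersion_start_s,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_recordings(manifest_path) -> list[Recording]:
    """Load and validate a cohort of recordings from a manifest TSV."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, sep="\t")
    need = {"subject_id", "file", "immersion_start_s"}
    if not need.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    out = []
    for _, row in man.iterrows():
        fpath = manifest_path.parent / row["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"recording file missing: {fpath}")
        df = pd.read_csv(fpath, sep="\t")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{fpath}: too few samples")
        dt = np.diff(t)
        if (dt <= 0).any():
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{fpath}: non-monotone time column at line {bad + 1}")
        if np.abs(dt - dt[0]).max() > 1e-6 * dt[0]:
            raise ValueError(f"{fpath}: irregular sampling interval")
        if df[["flow_au", "temp_c"]].isna().any().any():
            raise ValueError(f"{fpath}: NaN values in flow/temperature")
        out.append(
            Recording(
                subject_id=str(row["subject_id"]),
                rate_hz=1.0 / dt[0],
                immersion_start_s=float(row["immersion_start_s"]),
                flow=df["flow_au"].to_numpy(),
                temp=df["temp_c"].to_numpy(),
            )
        )
    return out


def write_vcf(g: GenotypeMatrix, path) -> Path:
    """Minimal VCF 4.2 with GT-only FORMAT; missing dosage becomes ./."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in pd.unique(g.variants["chrom"])]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.subjects)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j in range(g.n_variants):
        v = g.variants.iloc[j]
        gts = [
            gt_map.get(g.dosage[i, j], "./.") if not np.isnan(g.dosage[i, j]) else "./."
            for i in range(g.n_subjects)
        ]
        lines.append(
            f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
            f"\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path = Path(path)
    _atomic_write(path, "\n".join(lines) + "\n")
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT records; multiallelic records are skipped."""
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 unknown
    subjects = list(vcf.samples)
    var_rows, cols = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        var_rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,  # cyvcf2 POS is 1-based
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        gt = np.asarray(rec.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        cols.append(gt)
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic records")
    if not var_rows:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        subjects=subjects,
        variants=pd.DataFrame(var_rows),
        dosage=np.column_stack(cols),
    )


def write_dosage_tsv(g: GenotypeMatrix, path) -> Path:
    df = pd.DataFrame(g.dosage, index=g.subjects, columns=g.variants["id"])
    df.index.name = "subject_id"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA)
    return Path(path)


def write_truth_json(truth, path) -> Path:
    """Serialize a GroundTruth ledger (params objects are dropped)."""
    payload = truth.to_json_dict()
    for row in payload["subjects"]:
        row.pop("params", None)
        row.pop("achieved_ratios", None)
    _atomic_write(Path(path), json.dumps(payload, indent=1, default=str))
    return Path(path)


DEFAULT_CONFIG = {
    "signal": {
        "window_s": 60.0,
        "analysis_rate_hz": 5.0,
        "f_min": 0.005,
        "f_max": 0.150,
        "voices_per_octave": 16,
        "omega0": 6.0,
    },
    "detection": {
        "slope_thresh": 0.05,
        "sustain_s": 60.0,
        "temp_rise_c": 0.3,
        "phase2_cap_s": 600.0,
    },
    "qc": {"call_rate_min": 0.97, "hwe_alpha": 1e-4, "maf_min": 0.005},
    "assoc": {"n_perm": 1000, "gw": 5e-8, "borderline": 1e-5, "corstr": "ar1"},
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Default configuration, optionally updated from a JSON file.

    Unknown top-level keys or unknown keys inside a known section are
    rejected rather than silently ignored.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is None:
        return cfg
    user = json.loads(Path(path).read_text())
    for key, val in user.items():
        if key not in cfg:
            raise KeyError(f"unknown config key: {key}")
        if isinstance(cfg[key], dict):
            for k2 in val:
                if k2 not in cfg[key]:
                    raise KeyError(f"unknown config key: {key}.{k2}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def echo_config(cfg: dict, out_dir) -> Path:
    path = Path(out_dir) / "config_used.json"
    _atomic_write(path, json.dumps(cfg, indent=1))
    return path
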
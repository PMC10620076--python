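#!/usr/bin/env python
"""TI envelope dosimetry and the tTIS-vs-tDCS ROI comparison.

Loads the per-mA channel fields written by 02_solve_fields.py, forms
the TI maximum-modulation-envelope map at 2 mA per channel, summarizes
it over the deep target / cortical control / electrode-sphere ROIs, and
compares it with the static field magnitude of a conventional two-
electrode (C3 anodal, Fp2 cathodal) montage at 2 mA.
"""

from pathlib import Path

import numpy as np

import tidose
from tidose.nifti_io import read_volume, write_volume
from tidose.report import build_reports, compare_conditions, report_to_json
from tidose.solver import ChannelPair, VectorFieldVolume

ROOT = Path(__file__).resolve().parents[1]
FIELDS = ROOT / "results" / "fields"
OUT = ROOT / "results" / "exposure"

CURRENT_MA = 2.0  # per channel, peak to baseline


def load_field(ph, name):
    E, _ = read_volume(FIELDS / f"E_{name}.nii")
    return VectorFieldVolume(E=np.asarray(E, dtype=float), normalization_mA=1.0,
                             channel=name, spacing_mm=ph.spacing_mm)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ph = tidose.build_phantom(tidose.PhantomConfig(spacing_mm=2.0))
    f1 = load_field(ph, "F3-F4")
    f2 = load_field(ph, "TP7-TP8")
    ti = tidose.ti_envelope_map(f1, f2, CURRENT_MA, CURRENT_MA)
    write_volume(ti.values, ph.affine(), OUT / "ti_map.nii")

    rois = tidose.make_roi_set(ph)
    roi_masks = {n: rois[n] for n in
                 ("target", "target_left", "target_right",
                  "cortical_control", "brain")}
    for lbl in ("F3", "F4", "TP7", "TP8"):
        (el,) = tidose.electrode_positions([lbl], ph)
        roi_masks[f"sphere_{lbl}"] = tidose.sphere_under_electrode(
            ph, el, radius_mm=10.0)

    ti_reports = build_reports(ti.values, roi_masks,
                               metadata={"condition": "tTIS",
                                         "mA_per_channel": CURRENT_MA})
    report_to_json(ti_reports, OUT / "ti_roi_report.json")
    print(f"tTIS exposure at {CURRENT_MA:g} mA/channel:")
    for name in sorted(ti_reports):
        s = ti_reports[name].stats
        print(f"  {name:18s} mean {s.mean:.3f} +/- {s.sd:.3f} V/m, median "
              f"{s.median:.3f}, p99 {s.p99:.3f} (n={s.n_voxels})")

    # conventional two-electrode comparator: C3 anodal, Fp2 cathodal
    c3, fp2 = tidose.electrode_positions(["C3", "Fp2"], ph)
    pot, fld, inj = tidose.solve_channel(
        ph, ChannelPair(anode=c3, cathode=fp2), tol=1e-8)
    _, fld = tidose.normalize_current(pot, fld, inj, 1.0)
    tdcs = tidose.tdcs_magnitude_map(fld, CURRENT_MA)
    write_volume(tdcs, ph.affine(), OUT / "tdcs_map.nii")
    tdcs_reports = build_reports(tdcs, roi_masks,
                                 metadata={"condition": "tDCS",
                                           "mA": CURRENT_MA})
    table = compare_conditions(ti_reports, tdcs_reports,
                               label_a="ttis", label_b="tdcs")
    table.to_csv(OUT / "ttis_vs_tdcs.csv", index=False, float_format="%.6g")
    row = table[table["roi"] == "target"].iloc[0]
    print(f"target ROI: tTIS median {row['median_ttis']:.3f} V/m vs "
          f"tDCS |E| median {row['median_tdcs']:.3f} V/m")

    d_ti = tidose.argmax_depth_mm(ti.values, ph)
    d1 = tidose.argmax_depth_mm(f1.magnitude, ph)
    d2 = tidose.argmax_depth_mm(f2.magnitude, ph)
    print(f"interior arg-max depth: TI envelope {d_ti:.1f} mm vs channel "
          f"fields {d1:.1f} / {d2:.1f} mm below the scalp")
    print(f"wrote maps, reports and comparison to {OUT}")


if __name__ == "__main__":
    main()
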
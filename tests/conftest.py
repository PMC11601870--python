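import numpy as np
import pandas as pd
import pytest

from lipidflow.preprocess import FeatureTable
from lipidflow import simulate as sim

# Lipid names as printed in the study's figures and methods (incl. the
# internal-standard catalog); every one must parse.
PRINTED_LIPID_NAMES = [
    "Car 24:0", "Car 24:1", "Car 26:1",
    "Cer C16:0", "Cer C23:0",
    "FFA 20:4", "FFA 22:6", "FFA 24:1",
    "LPC 16:0", "LPC 18:1", "LPC 18:1(d7)",
    "LPE 16:0", "LPE 18:0", "LPE 18:1", "LPE 18:1(d7)", "LPE 20:4",
    "PC 16:0/16:0", "PC 16:0_14:0", "PC 16:0_16:1", "PC 16:0_18:1",
    "PC 18:0_22:6", "PC 32:1", "PC 40:6", "PC 15:0–18:1(d7)",
    "PE 18:0_22:5", "PE 18:0_22:6", "PE O-18:1_22:5", "PE 15:0–18:1(d7)",
    "PS 15:0–18:1(d7)", "PG 15:0–18:1(d7)", "PI 15:0–18:1(d7)",
    "DAG 15:0–18:1(d7)", "TAG 15:0–18:1(d7)-15:0",
    "SM 18:1(d9)", "SM d18:1/24:1", "SM d42:2",
    "TAG 48:0", "TAG 50:2", "TAG 56:6",
    "Chol Ester 18:1(d7)", "cholesterol (d7)",
]


def make_feature_table(areas, qc=None, blank=None, names=None,
                       msi_levels=None, tissue="LIVER", esi_mode="positive",
                       groups=None, sexes=None):
    """Small FeatureTable from a features x samples array plus optional QC
    and blank columns. Returns (table, meta)."""
    areas = np.asarray(areas, dtype=float)
    n_feat, n_study = areas.shape
    cols, roles, sample_ids = [], [], []
    blocks = []
    order = 1
    if blank is not None:
        blank = np.atleast_2d(np.asarray(blank, dtype=float))
        for j in range(blank.shape[1]):
            cols.append(f"blk{j}"); roles.append("blank"); sample_ids.append(None)
        blocks.append(blank)
    if qc is not None:
        qc = np.atleast_2d(np.asarray(qc, dtype=float))
        for j in range(qc.shape[1]):
            cols.append(f"qc{j}"); roles.append("QC"); sample_ids.append(None)
        blocks.append(qc)
    for j in range(n_study):
        cols.append(f"inj_s{j}"); roles.append("study"); sample_ids.append(f"s{j}")
    blocks.append(areas)
    mat = np.hstack(blocks)
    inj = pd.DataFrame({"order": np.arange(1, len(cols) + 1), "role": roles,
                        "sample_id": sample_ids}, index=cols)
    fid = [f"F{i}" for i in range(n_feat)]
    feats = pd.DataFrame({
        "name": names if names is not None else [f"PC 3{i}:1" for i in range(n_feat)],
        "msi_level": msi_levels if msi_levels is not None else [2] * n_feat,
        "esi_mode": esi_mode,
        "is_istd": False,
    }, index=fid)
    table = FeatureTable(areas=pd.DataFrame(mat, index=fid, columns=cols),
                         features=feats, injections=inj, tissue=tissue,
                         esi_mode=esi_mode)
    meta = pd.DataFrame({
        "group": groups if groups is not None else ["SED"] * n_study,
        "sex": sexes if sexes is not None else ["male"] * n_study,
    }, index=[f"s{j}" for j in range(n_study)])
    return table, meta


@pytest.fixture(scope="session")
def small_study():
    """One-tissue synthetic study with default planted effects."""
    design = sim.StudyDesign(tissues=("LIVER",), seed=11)
    return sim.simulate_study(design, seed=11)


@pytest.fixture(scope="session")
def null_study():
    design = sim.StudyDesign(tissues=("LIVER",), seed=13)
    return sim.simulate_study(design, effects=[], seed=13)
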
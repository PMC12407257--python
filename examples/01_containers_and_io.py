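"""Multimodal containers: alignment, epoching, evoked averaging, BIDS export.

Builds a synthetic EEG + fNIRS recording with mismatched sampling rates,
harmonizes it, cuts epochs around events and writes a BIDS-style tree.
"""

import tempfile
from pathlib import Path

import numpy as np

from neurofuse import (EventTable, Recording, align_timepoint, epoch, evoked,
                       io)
from neurofuse.simulate import sim_coupled_fnirs, sim_eeg

eeg = sim_eeg(channels=4, duration_s=60.0, rate=250.0, seed=0)
hb, _ = sim_coupled_fnirs(eeg, coupling=0.8, fnirs_rate=13.7, seed=1)
hb = hb.copy(start_time=0.0)

rec = Recording(blocks={"eeg": eeg, "nirs": hb},
                events=EventTable(np.arange(2.0, 55.0, 10.0), np.zeros(6),
                                  ["stim"] * 6),
                meta={"subject": "01", "task": "demo"})
rec = align_timepoint(rec)
print(f"aligned rates: eeg {rec.blocks['eeg'].rate} Hz, "
      f"nirs {rec.blocks['nirs'].rate:.4f} Hz")
print("  (the slow block is resampled so the fast/slow ratio is an integer)")

eps = epoch(rec.blocks["eeg"], rec.events, tmin=0.0, tmax=2.0)
ev = evoked(eps)
print(f"{eps.n_epochs} epochs of {eps.data.shape[2]} samples; "
      f"evoked block shape {ev.data.shape} (per-sample mean across trials)")

with tempfile.TemporaryDirectory() as tmp:
    sub = io.export_bids_layout(rec, Path(tmp))
    files = sorted(p.relative_to(tmp) for p in Path(tmp).rglob("*")
                   if p.is_file())
    print("BIDS-style export:")
    for f in files:
        print(f"  {f}")
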
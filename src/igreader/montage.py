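"""32-channel EEG montage: channel names, neighbour map, component topographies.

The montage uses standard 10–20-style labels for a 32-electrode equidistant
cap and includes the 13 central channels used for artifact thresholding
(F3, Fz, F4, FC1, FC2, C3, Cz, C4, CP1, CP2, P3, Pz, P4).  The neighbour
map lists, for every channel, the adjacent electrodes used when a bad
channel is rebuilt as the mean of its good neighbours.
"""

CHANNELS_32: list[str] = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
]

#: channels entering the per-participant rejection threshold
CENTRAL_CHANNELS: list[str] = [
    "F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4",
]

NEIGHBOURS: dict[str, list[str]] = {
    "Fp1": ["Fp2", "F7", "F3", "Fz"],
    "Fp2": ["Fp1", "F8", "F4", "Fz"],
    "F7": ["Fp1", "F3", "FC5", "T7"],
    "F3": ["Fp1", "F7", "Fz", "FC5", "FC1"],
    "Fz": ["Fp1", "Fp2", "F3", "F4", "FC1", "FC2"],
    "F4": ["Fp2", "F8", "Fz", "FC2", "FC6"],
    "F8": ["Fp2", "F4", "FC6", "T8"],
    "FC5": ["F7", "F3", "FC1", "T7", "C3"],
    "FC1": ["F3", "Fz", "FC5", "C3", "Cz"],
    "FC2": ["F4", "Fz", "FC6", "C4", "Cz"],
    "FC6": ["F8", "F4", "FC2", "T8", "C4"],
    "T7": ["F7", "FC5", "C3", "CP5", "TP9"],
    "C3": ["FC5", "FC1", "T7", "Cz", "CP5", "CP1"],
    "Cz": ["FC1", "FC2", "C3", "C4", "CP1", "CP2"],
    "C4": ["FC2", "FC6", "T8", "Cz", "CP2", "CP6"],
    "T8": ["F8", "FC6", "C4", "CP6", "TP10"],
    "TP9": ["T7", "CP5", "P7", "PO9"],
    "CP5": ["T7", "C3", "CP1", "P7", "P3", "TP9"],
    "CP1": ["C3", "Cz", "CP5", "P3", "Pz"],
    "CP2": ["C4", "Cz", "CP6", "P4", "Pz"],
    "CP6": ["T8", "C4", "CP2", "P8", "P4", "TP10"],
    "TP10": ["T8", "CP6", "P8", "PO10"],
    "P7": ["TP9", "CP5", "P3", "PO9", "O1"],
    "P3": ["CP5", "CP1", "P7", "Pz", "O1"],
    "Pz": ["CP1", "CP2", "P3", "P4", "O1", "Oz", "O2"],
    "P4": ["CP2", "CP6", "P8", "Pz", "O2"],
    "P8": ["TP10", "CP6", "P4", "PO10", "O2"],
    "PO9": ["TP9", "P7", "O1"],
    "O1": ["P7", "P3", "Pz", "Oz", "PO9"],
    "Oz": ["O1", "O2", "Pz"],
    "O2": ["P8", "P4", "Pz", "Oz", "PO10"],
    "PO10": ["TP10", "P8", "O2"],
}

#: spatial weight of the parietal positive-shift template per channel
EPS_PROFILE: dict[str, float] = {
    "Pz": 1.0, "P3": 0.70, "P4": 0.70, "CP1": 0.60, "CP2": 0.60,
    "Cz": 0.45, "CP5": 0.35, "CP6": 0.35, "C3": 0.30, "C4": 0.30,
    "O1": 0.30, "Oz": 0.35, "O2": 0.30, "P7": 0.30, "P8": 0.30,
    "FC1": 0.20, "FC2": 0.20, "Fz": 0.15,
}

#: spatial weight of the frontal P200 template per channel
P200_PROFILE: dict[str, float] = {
    "Fz": 1.0, "F3": 0.70, "F4": 0.70, "FC1": 0.60, "FC2": 0.60,
    "Fp1": 0.35, "Fp2": 0.35, "F7": 0.30, "F8": 0.30, "Cz": 0.40,
    "FC5": 0.30, "FC6": 0.30,
}
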
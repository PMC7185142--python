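region,network
L.amPFC,DN
R.amPFC,DN
L.dmPFC,DN
R.dmPFC,DN
L.vmPFC,DN
R.vmPFC,DN
L.pCC,DN
R.pCC,DN
L.pIPL,DN
R.pIPL,DN
L.aTL,DN
R.aTL,DN
L.HF,DN
R.HF,DN
L.STS,DN
R.STS,DN
L.rlPFC,CN
R.rlPFC,CN
L.dlPFC,CN
R.dlPFC,CN
L.aINS,CN
R.aINS,CN
L.daCC,CN
R.daCC,CN
L.aIPL,CN
R.aIPL,CN
L.msPFC,CN
L.PCu,CN
L.TPJ,CN
L.IFG,CN
L.FEF,AN
R.FEF,AN
L.iPCS,AN
R.iPCS,AN
L.MT,AN
R.MT,AN
L.SPL,AN
R.SPL,AN
L.SOG,AN
R.SOG,AN
R.SFG,AN
R.MFG(BA6),AN
R.MFG(BA9),AN
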
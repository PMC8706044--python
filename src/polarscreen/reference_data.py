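"""Curated reference-standard panel for *Lemna minor* screening.

A panel of 42 duckweed metabolites (amino acids, vitamins, flavonoid
aglycons and glycosides) validated by reference-standard injection on a
polarity-extended RPLC-HILIC separation: for each compound, the
retention time and [M+H]+ mass of the injected standard and of the
matched sample feature, plus the characteristic MS/MS fragments.  Useful
as a realistic worked example for the deviation report and the column
partition (16 compounds elute from the HILIC column before 15 min, 26
from the RPLC column after).

The serine row's measured mass carries a transcription artifact (shifted
by ~10 Da against its standard mass); it is retained verbatim but should
be excluded from mass-deviation statistics.
"""

from __future__ import annotations

import io

import pandas as pd

_PANEL_CSV = """name	rt_standard_min	rt_measured_min	mass_standard	mass_measured	fragments	in_system_a
Vitexin	7.5	7.3	433.1133	433.1129	433;415;397;379;337;313;283	False
Niacin	7.6	7.8	124.0394	124.0393	124;96;80;78	True
Nicotinamide	7.8	7.6	123.0554	123.0553	123;106;80;78	False
Phenylalanine	11.0	11.1	166.0866	166.08627	120;103;77	True
Leucine/Isoleucine	11.2	11.2	132.1018	132.1020	86;69;44;30	True
Tryptophan	11.7	11.7	205.0973	205.0970	188;146;144	True
Valine	12.1	11.9	118.0863	118.0862	72;71;55	True
Tyrosine	12.3	12.2	182.0811	182.0810	136;123;119	True
Proline	12.4	12.4	116.0705	116.0707	70;68;43	True
Glutamic acid	12.5	12.6	147.0434	147.0430	130;102;84	True
Aspartic acid	12.7	12.7	134.0447	134.0447	134;115	True
Di-L-Alanine	12.7	12.8	161.0928	161.0920	161;115;90	False
4-Methoxy cinnamic acid	13.4	13.1	179.0706	179.0708	147;137	False
Alanine	13.4	13.2	90.0550	90.0548	44;28	True
Threonine	13.6	13.4	120.0656	120.0653	73;56	True
Serine	14.0	13.8	106.0500	116.0499	60;42;43	True
Apigenin-6,8-di-C-glucopyranoside	15.8	15.7	595.1659	595.1658	595;383	True
Robinetin	15.8	15.9	303.0494	303.0493	285;267;147	False
Apigenin-6-C-arabopyranoside-8-C-glucopyranose	23.4	23.3	565.1550	565.1557	565;547;379;337;325;295;121	False
Luteolin-3',7-di-O-glucoside	23.8	23.6	611.1640	611.1622	611;449;287	False
Saponarin	23.8	24.0	595.1638	595.1663	433;415;397;367;337;283;271	False
Isoorientin	23.8	23.6	449.1085	449.1095	449;329;299;165	False
Isovitexin	24.1	23.9	433.1125	433.1134	313;295;284;283;267	False
Norwogonin	24.2	24.0	271.0604	271.0599	271;253;241;225	False
Quercetin-3-O-glucoside	24.2	24.3	465.1018	465.1022	465;303	False
Apiin	24.6	23.8	565.1566	565.1559	433;313	False
Umbelliferone	24.7	24.4	163.0396	163.0391	135;107	False
Quercetin	24.8	24.9	303.0549	303.0544	303;285;257;229;165	False
Luteolin	24.8	24.6	287.0562	287.0557	287;269;241;153	False
Naringenin-7-O-glucoside	25.0	24.1	435.1298	435.1285	435;273	False
Myricetin	25.1	25.1	319.0440	319.0453	301;283;265;111	False
Orientin	25.1	25.2	449.1123	449.1134	449;329	False
Peonidin	25.6	25.2	302.0785	302.0792	302;283;197	False
Chrysoeriol	26.9	26.8	301.0731	301.0722	286;121	False
Tricin	26.8	26.3	331.0811	331.0796	331;315	False
Apigenin	26.8	26.7	271.0603	271.0604	271;253;153	False
Acacetin	28.8	29.1	285.0759	285.0760	285;242;153	False
Kaempferol	29.0	29.1	287.0531	287.0540	287;269;231;165;153;133	False
Galangin	29.4	29.4	271.0602	271.0608	271;253	False
Flavone	29.9	29.6	223.0756	223.0748	223;178;152;121	False
6-Methoxyflavone	30.4	30.6	253.0879	253.0881	253;238;210	False
5-Hydroxy-6-Methoxyflavone	31.3	31.1	269.0823	269.0819	269;254;104	False
"""

#: Panel rows whose measured mass is internally inconsistent and must be
#: excluded from ppm statistics (see module docstring).
MASS_DISCREPANT = ("Serine",)


def lemna_reference_panel() -> pd.DataFrame:
    """The 42-compound validated panel as a DataFrame.

    Columns: ``name``, standard and measured RT (min), standard and
    measured mass (Da, [M+H]+ scale), ``fragments`` (';'-separated m/z)
    and ``in_system_a`` (also detected on the single-TOF system).
    """
    df = pd.read_csv(io.StringIO(_PANEL_CSV), sep="\t")
    df["in_system_a"] = df["in_system_a"].astype(bool)
    return df
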
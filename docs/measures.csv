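key,unit,kind,description
Me-rGo,mm,distance,Length of the mandible (menton to right gonion)
rGo-lGo,mm,distance,Width of the mandible (right to left gonion)
Na-B,mm,distance,Anteroposterior position of the mandible (nasion to B point)
Na-A,mm,distance,Anteroposterior position of the maxilla (nasion to A point)
AB-shift,mm,signed distance,Anteroposterior shift: x_A - x_B of the Frankfort-plane projections (negative for a protrusive mandible)
S-Na,mm,distance,Cranial base dimension (sella to nasion)
C3-H,mm,distance,Hyoid bone to the third cervical vertebra
Me-H,mm,distance,Hyoid bone to menton
H-PNS,mm,distance,Hyoid bone to posterior nasal spine
S-H,mm,distance,Hyoid bone to sella
rTb-lTb,mm,distance,Maxilla width between the tuberosities
rCN-lCN,mm,distance,Nasal cavity width
Na-ANS,mm,distance,Nasal cavity height (nasion to anterior nasal spine)
BEP-A,mm,distance,Tongue height (base of epiglottis to A point)
BEP-TUV,mm,distance,Tongue width (base of epiglottis to uvula tip)
HSP,mm,horizontal offset,Horizontal soft palate: |x_PNS - x_LP| to the most posterior soft-palate point
TUV-PNS,mm,distance,Soft palate length (uvula tip to posterior nasal spine)
Ba-Tph,mm,distance,Pharyngeal soft-tissue thickness (basion to pharyngeal hypertrophy point)
VSP,mm,vertical offset,Vertical soft palate: |z_PNS - z_TUV| to the soft-palate tip
SNA,deg,angle,Maxillary prognathism (S-Na-A)
SNB,deg,angle,Mandibular prognathism (S-Na-B)
SNPg,deg,angle,Facial angle (S-Na-Pg)
FMA,deg,angle,Frankfort-mandibular plane angle (sagittal projections of rPo-rOr and Me-rGo)
H-S-Ba,deg,angle,Hyoid angle at sella
H-Na-S,deg,angle,Hyoid angle at nasion
age,years,covariate,Subject age (pass-through)
sex,0/1,covariate,Subject sex (1 = female; pass-through)
Vol,mm^3,airway metric,Airway volume between the palatal plane and the C3 plane
CSAmin,mm^2,airway metric,Minimal axial cross-sectional area of the airway
Ap,mm,airway metric,Anteroposterior (sagittal) extent of the minimal slice
Lat,mm,airway metric,Lateral (coronal) extent of the minimal slice
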
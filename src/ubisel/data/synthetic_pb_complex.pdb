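NUMMDL    2                                                                     
REMARK 999 SYNTHETIC schematic two-chain complex fixture for geometry tests.
REMARK 999 NOT a real structure: residue placement is artificial. Model 1 puts
REMARK 999 the ASP 833 OD1 atom 3.69 A from the ARG 510 NH1 atom (side-chain
REMARK 999 minimum) and the ASP 833 N atom closer still (all-atom minimum);
REMARK 999 model 2 shifts chain A by -0.19 A along x.
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1                      
MODEL        1                                                                  
ATOM      1  N   TYR A 818       9.000   8.000   0.000  1.00  0.00           N  
ATOM      2  CA  TYR A 818      10.000   8.500   0.000  1.00  0.00           C  
ATOM      3  C   TYR A 818      11.000   8.000   0.500  1.00  0.00           C  
ATOM      4  O   TYR A 818      12.000   8.500   0.500  1.00  0.00           O  
ATOM      5  CB  TYR A 818      10.200  10.000   0.000  1.00  0.00           C  
ATOM      6  CG  TYR A 818      10.400  11.400   0.000  1.00  0.00           C  
ATOM      7  OH  TYR A 818      10.800  14.000   0.000  1.00  0.00           O  
ATOM      8  N   GLY A 820       4.500   6.000   0.000  1.00  0.00           N  
ATOM      9  CA  GLY A 820       5.500   6.800   0.000  1.00  0.00           C  
ATOM     10  C   GLY A 820       6.800   6.200   0.300  1.00  0.00           C  
ATOM     11  O   GLY A 820       7.800   6.900   0.200  1.00  0.00           O  
ATOM     12  N   ASP A 833       2.900  -1.500   0.000  1.00  0.00           N  
ATOM     13  CA  ASP A 833       7.100   1.300   0.000  1.00  0.00           C  
ATOM     14  C   ASP A 833       7.300   2.400   1.000  1.00  0.00           C  
ATOM     15  O   ASP A 833       7.000   3.600   0.800  1.00  0.00           O  
ATOM     16  CB  ASP A 833       6.000   0.300   0.000  1.00  0.00           C  
ATOM     17  CG  ASP A 833       4.600   0.800   0.000  1.00  0.00           C  
ATOM     18  OD1 ASP A 833       3.690   0.000   0.000  1.00  0.00           O  
ATOM     19  OD2 ASP A 833       4.400   2.000   0.100  1.00  0.00           O  
ATOM     20  N   ARG B 510      -8.400   0.100   0.000  1.00  0.00           N  
ATOM     21  CA  ARG B 510      -7.200  -0.600   0.000  1.00  0.00           C  
ATOM     22  C   ARG B 510      -7.400  -1.600   1.000  1.00  0.00           C  
ATOM     23  O   ARG B 510      -7.000  -2.800   0.900  1.00  0.00           O  
ATOM     24  CB  ARG B 510      -6.000   0.200   0.000  1.00  0.00           C  
ATOM     25  CG  ARG B 510      -4.800  -0.600   0.000  1.00  0.00           C  
ATOM     26  CD  ARG B 510      -3.600   0.200   0.200  1.00  0.00           C  
ATOM     27  NE  ARG B 510      -2.300  -0.400   0.000  1.00  0.00           N  
ATOM     28  CZ  ARG B 510      -1.000   0.000   0.000  1.00  0.00           C  
ATOM     29  NH1 ARG B 510       0.000   0.000   0.000  1.00  0.00           N  
ATOM     30  NH2 ARG B 510      -1.600   1.200   0.000  1.00  0.00           N  
ATOM     31  N   LEU B 514      -6.000   6.000   0.000  1.00  0.00           N  
ATOM     32  CA  LEU B 514      -5.000   6.800   0.000  1.00  0.00           C  
ATOM     33  C   LEU B 514      -4.000   6.300   0.600  1.00  0.00           C  
ATOM     34  O   LEU B 514      -3.000   6.900   0.800  1.00  0.00           O  
ATOM     35  CB  LEU B 514      -5.200   8.300   0.000  1.00  0.00           C  
ATOM     36  CG  LEU B 514      -5.400   9.000   1.200  1.00  0.00           C  
ATOM     37  CD1 LEU B 514      -5.600  10.500   1.000  1.00  0.00           C  
ATOM     38  CD2 LEU B 514      -6.500   8.600   2.200  1.00  0.00           C  
ENDMDL                                                                          
MODEL        2                                                                  
ATOM      1  N   TYR A 818       8.810   8.000   0.000  1.00  0.00           N  
ATOM      2  CA  TYR A 818       9.810   8.500   0.000  1.00  0.00           C  
ATOM      3  C   TYR A 818      10.810   8.000   0.500  1.00  0.00           C  
ATOM      4  O   TYR A 818      11.810   8.500   0.500  1.00  0.00           O  
ATOM      5  CB  TYR A 818      10.010  10.000   0.000  1.00  0.00           C  
ATOM      6  CG  TYR A 818      10.210  11.400   0.000  1.00  0.00           C  
ATOM      7  OH  TYR A 818      10.610  14.000   0.000  1.00  0.00           O  
ATOM      8  N   GLY A 820       4.310   6.000   0.000  1.00  0.00           N  
ATOM      9  CA  GLY A 820       5.310   6.800   0.000  1.00  0.00           C  
ATOM     10  C   GLY A 820       6.610   6.200   0.300  1.00  0.00           C  
ATOM     11  O   GLY A 820       7.610   6.900   0.200  1.00  0.00           O  
ATOM     12  N   ASP A 833       2.710  -1.500   0.000  1.00  0.00           N  
ATOM     13  CA  ASP A 833       6.910   1.300   0.000  1.00  0.00           C  
ATOM     14  C   ASP A 833       7.110   2.400   1.000  1.00  0.00           C  
ATOM     15  O   ASP A 833       6.810   3.600   0.800  1.00  0.00           O  
ATOM     16  CB  ASP A 833       5.810   0.300   0.000  1.00  0.00           C  
ATOM     17  CG  ASP A 833       4.410   0.800   0.000  1.00  0.00           C  
ATOM     18  OD1 ASP A 833       3.500   0.000   0.000  1.00  0.00           O  
ATOM     19  OD2 ASP A 833       4.210   2.000   0.100  1.00  0.00           O  
ATOM     20  N   ARG B 510      -8.400   0.100   0.000  1.00  0.00           N  
ATOM     21  CA  ARG B 510      -7.200  -0.600   0.000  1.00  0.00           C  
ATOM     22  C   ARG B 510      -7.400  -1.600   1.000  1.00  0.00           C  
ATOM     23  O   ARG B 510      -7.000  -2.800   0.900  1.00  0.00           O  
ATOM     24  CB  ARG B 510      -6.000   0.200   0.000  1.00  0.00           C  
ATOM     25  CG  ARG B 510      -4.800  -0.600   0.000  1.00  0.00           C  
ATOM     26  CD  ARG B 510      -3.600   0.200   0.200  1.00  0.00           C  
ATOM     27  NE  ARG B 510      -2.300  -0.400   0.000  1.00  0.00           N  
ATOM     28  CZ  ARG B 510      -1.000   0.000   0.000  1.00  0.00           C  
ATOM     29  NH1 ARG B 510       0.000   0.000   0.000  1.00  0.00           N  
ATOM     30  NH2 ARG B 510      -1.600   1.200   0.000  1.00  0.00           N  
ATOM     31  N   LEU B 514      -6.000   6.000   0.000  1.00  0.00           N  
ATOM     32  CA  LEU B 514      -5.000   6.800   0.000  1.00  0.00           C  
ATOM     33  C   LEU B 514      -4.000   6.300   0.600  1.00  0.00           C  
ATOM     34  O   LEU B 514      -3.000   6.900   0.800  1.00  0.00           O  
ATOM     35  CB  LEU B 514      -5.200   8.300   0.000  1.00  0.00           C  
ATOM     36  CG  LEU B 514      -5.400   9.000   1.200  1.00  0.00           C  
ATOM     37  CD1 LEU B 514      -5.600  10.500   1.000  1.00  0.00           C  
ATOM     38  CD2 LEU B 514      -6.500   8.600   2.200  1.00  0.00           C  
ENDMDL                                                                          
END                                                                             
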
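# Pool of tryptic peptide sequences (K/R C-termini, standard 20-letter alphabet)
# used by the simulator so that elemental compositions are peptide-realistic.
LVNELTEFAK
YLYEIAR
AEFVEVTK
QTALVELLK
HLVDEPQNLIK
LGEYGFQNALIVR
KVPQVSTPTLVEVSR
DAFLGSFLYEYSR
YICDNQDTISSK
LFTFHADICTLPDTEK
ECCHGDLLECADDR
SLHTLFGDELCK
VLTSSAR
QNCDQFEK
LGGNEQVTR
AVDDFLISLDGTANK
SVQEIQATFFYFTPNK
GITWGEETLMEYLENPK
TGPNLHGLFGR
IFVQKCAQCHTVEK
GEREDLIAYLK
TEREDLIAYLKK
ATNHIIVATPGR
NALESYAFNMK
SEIAHRFK
DLGEEHFK
LCVLHEK
YNGVFQECCQAEDK
ALVLIAFAQYLQQCPFEDHVK
ETYGDMADCCEK
QEPERNECFLSHK
DDPHACYSTVFDK
LKPDPNTLCDEFK
VHKECCHGDLLECADDRADLAK
YANKYNGVFQECCQAEDK
ALKAWSVAR
LSQKFPK
AEFAEVSK
MPCTEDYLSLILNR
RPCFSALTPDETYVPK
AFDEKLFTFHADICTLPDTEK
QTALAELVK
YLYEIARR
HPEYAVSVLLR
LAKEYEATLEECCAK
DDPHACYATVFDK
GLVLIAFSQYLQK
CASIQKFGER
ALKAWSVARLSQK
FGERALKAWSVAR
AWSVARLSQKFPK
VTKCCTESLVNR
MPCTEDYLSLILNRLCVLHEK
DVCKNYQEAK
DAIPENLPPLTADFAEDKDVCK
NYQEAKDAFLGSFLYEYSR
RHPEYAVSVLLRLAK
EYEATLEECCAKDDPHACYSTVFDK
LVTDLTK
VHTECCHGDLLECADDRADLAK
YNGVFQECCQAEDKGACLLPK
IETMREK
VLASSARQR
LRCASIQK
FGDELCKVASLR
ETYGDMADCCEKQEPER
NECFLSHKDDSPDLPK
LKPDPNTLCDEFKADEK
KFWGKYLYEIAR
RHPYFYAPELLYYANK
YNGVFQECCQAEDKGACLLPKIETMR
EKVLASSARQR
LRCASIQKFGER
ALKAWSVARLSQKFPKAEFAEVSK
LVNELTEFAKTCVADESHAGCEK
SLHTLFGDELCKVASLRETYGDMADCCEK
QEPERNECFLSHKDDSPDLPKLKPDPNTLCDEFK
ADEKKFWGK
YLYEIARRHPYFYAPELLYYANKYNGVFQECCQAEDK
GACLLPKIETMREK
VLASSARQRLR
CASIQKFGERALK
AEFAEVSKLVTDLTK
GAGAFGYFEVTHDITK
YNELTEFAK
SHCIAEVEK
DAIPENLPPLTADFAEDK
DVFLGMFLYEYAR
TPVSDRVTK
CCTESLVNR
RPCFSALEVDETYVPK
EFNAETFTFHADICTLSEK
ERQIKKQTALVELVK
HKPKATEEQLK
TVMENFVAFVDK
CCAADDKEACFAVEGPK
LVVSTQTALA
SGEGDFLAEGGGVR
GPRVVERHQSACK
DSGRDYVSQFEGSALGK
QLVKDLTTAK
GITFSIPR
NLDKEYLPIGGLAEFCK
SAGWNIPIGLLYCDLPEPR
KPLDGEYFTLQIR
TSEKFQLSK
NVPLYKHLADLSK
SFYLNYAK
DMGIGGLTTK
VIDSGDGVTHTVPIYEGYALPHAILR
LDLAGRDLTDYLMK
ILTERGYSFTTTAER
EIVRDIK
EKLCYVALDFEQEMATAASSSSLEK
SYELPDGQVITIGNER
FRCPEALFQPSFLGMESCGIHETTFNSIMK
CDVDIRKDLYANTVLSGGTTMYPGIADR
MQKEITALAPSTMK
IKIIAPPERK
YSVWIGGSILASLSTFQQMWISK
QEYDESGPSIVHRK
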
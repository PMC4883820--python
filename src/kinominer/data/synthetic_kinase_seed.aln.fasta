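>AGC_seed1 synthetic seed alignment row
WNPYEWKSVRNISRMCAIHGHWDKVFNCVIFQHRAYCYWAEYLVMQQESTQRHWQQEFFS
PFVAGILLMQDWNMIHAGVAPAQCCYGEIKYFWNALQISWMDPCHIGTVAWNCHKNASFR
>AGC_seed2 synthetic seed alignment row
TNPYQWVMVRNISAMMAYHGHWDKVINCMIFQHRAYCYWAENLVMQQESTQRYWQQEFFS
FFVAGILGMQDWNMIHANVAPAQCCYGWIKYFENHLQISWMDPCHWGTVAWNCHKNASFR
>AGC_seed3 synthetic seed alignment row
TNPYQWKMVRFISAMMAEHGHWHKVRNCMIFQHRAYCYWAENLVNQQESRQRHWSQEFGS
FFVAGILLMQDWNMIHANVAPAQCCSGHIKY----LQISWMDPCHWGTVAWNCHKNTSFR
>CAMK_seed1 synthetic seed alignment row
TNPYLWHFVLGYHPDMVCQGLDSNMFLQSWQHNWAYAVTPSELCMFNSAFQKYFENLRIM
YYVATSMQDATHLRPFARSLHCGCINQWAWNQWLALQQEWSDCCATFTWAWRWNMKFFRG
>CAMK_seed2 synthetic seed alignment row
TNPYLWHTVLNQHADMVCEGLWSNMFYQQWQHNWAYAVFWSELCMFKSAFQKYFDNLRIM
YYVVTSPQDQTHLRPFHRSSHCGCINDTAWNQWLALRIEWSDCCATFTWCWRCNMKFHRG
>CAMK_seed3 synthetic seed alignment row
TNPAEWHFHLNYHPDMVCQGLWQNMFSQSWQHNWAYAVTWSELCMFNSASQKYFENVRIM
YEVATSMQDQTHLPPGARSSHCGCINQWAWNQWLALQIEWSDCCRTFTWAWRWNMKFHRG
>CMGC_seed1 synthetic seed alignment row
TNPELWVIYGFYSYAMPYWGGYEFMINTMMIPHGAQAPHASGLRMPGLCTQRGAQNHRTG
SKVIGTFQDQTRLKIDAGTDFRGMGEGWANMQMLANYIEESNYPHDFVCAWNPGMNIEHQ
>CMGC_seed2 synthetic seed alignment row
TNPELWVKYRFYSYAEPYWGGYEFMINTMMIPHGARAPHASGLRMPQESWQRGAQNERYG
WKVIGQFTDQTRLKIDAGTDFQSMNERWANCQWLANYIEESQYCHDFVCAWNAGVNIEHQ
>CMGC_seed3 synthetic seed alignment row
GNPELWVKYGSYSYFMAYWGGYEFMINTMDIPHGARAPQASGLRMPQDSTQRGAQNMRYG
SKVIGQFQDQTRLKIDAMTDFQGMEEGRANMQWLANYGEEWQYCHDFVCAKNAGMNIEHQ
>CK1_seed1 synthetic seed alignment row
CCNYQHHKVVFLSYGDPYFGYWDFMANRMEMKVGFYSKYAEHLDAFVWSRQRYAQYMRQA
ILDAGYNRDIAPCRIRTVKPWQTMGPGCHPEDILAKQICQMFPCHWFNCNWPCYLGIGHS
>CK1_seed2 synthetic seed alignment row
CCNYEHHKVVFLSYGDPYIGHWDFSECRMEMKVGFYSPYAEEEDAFVWSRQRYDQYMRQA
IKDRGYYYDIADCRIRTSKPWQTMGPGIHPSDIRAKQIEQSQPCHWFPCCWNCSLGIGHQ
>CK1_seed3 synthetic seed alignment row
CCKYQHHKVVFLSYGPPYFGHWQFSAPRMEMKVGFYS----ELDAFVWSRQRYAQYMRQA
IKDAGYNQDIAPRRSRTVKPWQTMRPGIHPSVILAKQIEQSFPCHWFPCCWNCSLGIGHQ
>RGC_seed1 synthetic seed alignment row
NLCYKWNKFKNFSPMYRGYVSHRYMMFMMMSPHGAYAVHAEHLRMDKKSTQNGWFNYRMG
WCVAPIFDDDAPLLIHANMSPDVMGEGGAPSAWRAGQIELMIPCDWWTIARWSYMNTEHI
>RGC_seed2 synthetic seed alignment row
LICYKWNKFRNYSPHYRGYVSHWYMCLAMMSPHGAYAVDAEHLRMFGKSTQTGSFNQRMG
WCVAPIFDDDAPLLIRANMSPWVMGEGGAPSAWRAGQIEIMMPCDWWTIARWSYMNIEHI
>RGC_seed3 synthetic seed alignment row
NLTIKWNLFRNYSPMYKGYVSHRYMCNAGLSYHGAYAVDAEHLRMFDKSTQNGEQNYRMG
WCVTPIFVDRAPLLIHENFSPWSMGEGGPTSAWAAGQIECMMPCDWWTIARWIYLNIEHH
>TK_seed1 synthetic seed alignment row
IAPGQMIKVLCYGPMMYGYQYMVQNLNNMQQWHSAYLPFHGELAMWLVMTSRFNHNEWGG
AKPFPEFVHDTSFFPHNVNSDNHMSEEWAPSQSIGEQIEWLCENPWFEPAIVRNMEIVNP
>TK_seed2 synthetic seed alignment row
IAPLEVIKVLCWNPMLYGYYYMWQMLNPMQQWMGASAPMSNELAMWLVMTSRFNQNEWYG
AKPFPEFVHDTVFFPHNVNSWNHMGEEYAPSRSIGEQIEWLIPCHWFEPAIVRHDEIENH
>TK_seed3 synthetic seed alignment row
IAMGYVIKVLCFNPMMQGYQYMVYMLNNMQQWHGAYAPFSTEIAMWKVMTSRFNQNEWYG
AKPFPKFVHDTVFFPHNVNSDNHMGEEWHPSQSIGEQIEWLCPCHWDEPAIVRHMEIENK
>TKL_seed1 synthetic seed alignment row
PNPSQWHPIIWYIDPVPEQNHWDQMANIEKHPNIAYPPSARELYSQPRSEVCQCQNECAD
FAAAYYSTDIHPLTIHHNSKAAGMGPGWKPSHMLQLQREWSDMLEWFMCDWTAHMNNYIW
>TKL_seed2 synthetic seed alignment row
INPSQWHPIIDYQDPVPEQSHWDQLAITGKQPNIAYAGSAFEYYSFFRGEVCNCQNQCAD
FIDAKYSRDIYPLTIHHISKAAGSGPDWKPSHMLQLQREWSDMLEWGMCDWTTHMNNYIW
>TKL_seed3 synthetic seed alignment row
ANPDQWHPIIDYQDPVPEQNHWDQMAVFGKQPNIAYAPSAREPYMFPRSKVCQDQFECAD
FADAYYSRDIHPLTIHHISKAAGMGPGQKPSHMLQLQREWSDMLEWFMCDWTWHMNNYIW
>STE_seed1 synthetic seed alignment row
MNPSQWIKVLMAYPMMPPDGDRDQMANTMCPNHSAYCPTYEELRSFQDSTSRIYMNERKD
MWVAFYFFVQVPLWINLNFSPVGMGEMKQPSSWLASQYESMEPCHWFTEGTKWRFRWNHI
>STE_seed2 synthetic seed alignment row
MNPSQWIKVLMAYPMMPPDFDCDQMANTMYPNHGAYWPTYEELRSFLDSTSRIYMNVRKD
MWVAFYFYVYTPLWINLSFGPRGMGEMKAPSSWLACQYESMEPCHWPTCGTKCRYNWNHI
>STE_seed3 synthetic seed alignment row
MNPSQWIKVLMAYPMMPWDGDCDQMANTCYPNHGAYCPTSEELRSFSDSTSRIYMNERKD
MWVAFYFTVGTPLWINLNFYM----EMKAPSSWVASQYESMEPCHWFTEGTKWRHSWNHI
>Other_seed1 synthetic seed alignment row
EPDYSWHLGLNYSPVRPGCPIYIQMCYTASNPPIAYPVHPMELYMYLESQTRCVQNECYE
INVLNQLFSQYILRIGAARPPRGMGQEWRLNLWYLLQIQWSDPAMWFEPAWYWDMNPEHI
>Other_seed2 synthetic seed alignment row
EPDYQCHLGLNYSPVAPGCPIYIQMCLTTSNPHIAYPVHPMELYMKQESQQRCVQNECYE
INVLNQFYSQRILRIGAARQPRLMGQEWRLCLFYLLQIQWSDPAHWCEPAWYWDMNEEHI
>Other_seed3 synthetic seed alignment row
EPDYQWHLGLNYSPVRPGCPIYIQMCLTASNPHIAYPCPPMELGMYQESQQFWVQTECYE
INVLDQLYSQYILRIGAARPPDGMGQEWRLCLWYLLQFQWSDPAHWCEPAWYWDMNPCHI
>aPK_seed1 synthetic seed alignment row
FNPNQAHKYTCYLIMYPGWGRRDGMANTMLWLRVNLAPHCKWLRCFQHSTQLNFPKESEW
FKVEGGFESQRPPRIHAMRPPQGMFKSWGPHPFLAFQWYSSNPCHSPTCAWNWKMNIEHI
>aPK_seed2 synthetic seed alignment row
FMPNQFHKYTCYEIMYPGWPTWDGMMNTELYPPVNGAPHCDIFRMFQHSTQRNFPKESCW
FKVAGGFESQRPPRIHAMRPKQGMFKQWRPMQFLALGWYSSVPCHSPTVAQNWKMNIEHI
>aPK_seed3 synthetic seed alignment row
FNPNQFHKRTCYLIMYPGWGTWTGMANTMLYPRVALKPHCDWLRMFQHSTQRNFPQEMCW
FKVAGGFESQRPPRIHAMQPPQIMFKQWCVHQFLALIWYSSVPCHSPTAAWNWKMNLEHI
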
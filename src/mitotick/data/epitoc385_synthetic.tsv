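#name=epitoc385-synthetic
#note=SYNTHETIC stand-in CpG list for the 385-probe mitotic clock; the published probe set ships with its source publication. Replace with the real list for array data.
#intercept=0.0
#calibration=identity
cpg_id	weight
cg10094850	
cg10208869	
cg10279967	
cg10318441	
cg10358948	
cg10373590	
cg10415162	
cg10429039	
cg10446293	
cg10512932	
cg10520248	
cg10527194	
cg10536291	
cg10690161	
cg10783377	
cg10812822	
cg10864697	
cg10891646	
cg10900565	
cg10903145	
cg10980128	
cg11013053	
cg11166648	
cg11175801	
cg11217008	
cg11227826	
cg11269705	
cg11284991	
cg11289073	
cg11330994	
cg11360744	
cg11490766	
cg11686581	
cg11690050	
cg11757933	
cg11816144	
cg11817898	
cg11835164	
cg11838879	
cg11912519	
cg12184524	
cg12216120	
cg12264592	
cg12324007	
cg12352439	
cg12375258	
cg12379760	
cg12549834	
cg12598092	
cg12722653	
cg12753554	
cg12798814	
cg12815906	
cg13080892	
cg13322585	
cg13326725	
cg13330225	
cg13476880	
cg13629396	
cg13642365	
cg13762026	
cg13791210	
cg13809766	
cg13872515	
cg13916562	
cg13925955	
cg13963957	
cg14019047	
cg14069846	
cg14089498	
cg14112098	
cg14319144	
cg14325570	
cg14412804	
cg14415142	
cg14501149	
cg14503424	
cg14583291	
cg14615983	
cg14633336	
cg14704146	
cg14728405	
cg14774228	
cg14826127	
cg14870087	
cg14886729	
cg14895988	
cg14969621	
cg15127574	
cg15135542	
cg15168246	
cg15196545	
cg15205558	
cg15212184	
cg15346344	
cg15352760	
cg15368432	
cg15489054	
cg15617779	
cg15664920	
cg15724537	
cg15775923	
cg15918821	
cg15945826	
cg15957665	
cg15998234	
cg16055998	
cg16130585	
cg16146269	
cg16186754	
cg16262184	
cg16305682	
cg16317032	
cg16328643	
cg16470938	
cg16506800	
cg16585859	
cg16590448	
cg16629899	
cg16702057	
cg16738997	
cg16834325	
cg16837268	
cg16871638	
cg16900430	
cg16908323	
cg16916892	
cg16970687	
cg17034926	
cg17054860	
cg17078163	
cg17080285	
cg17132470	
cg17190420	
cg17211141	
cg17225761	
cg17368781	
cg17401701	
cg17468034	
cg17631181	
cg17744882	
cg17873704	
cg17875751	
cg17964910	
cg18030763	
cg18124421	
cg18137681	
cg18239430	
cg18289740	
cg18312760	
cg18330522	
cg18375543	
cg18405286	
cg18432199	
cg18502268	
cg18523934	
cg18578072	
cg18718649	
cg18744795	
cg18800586	
cg18889997	
cg18901896	
cg18909113	
cg19189215	
cg19251209	
cg19263867	
cg19281172	
cg19374145	
cg19374770	
cg19378559	
cg19393594	
cg19406773	
cg19433001	
cg19456877	
cg19462836	
cg19499467	
cg19501847	
cg19609987	
cg19701022	
cg19917430	
cg19948846	
cg20242057	
cg20327960	
cg20353305	
cg20545331	
cg20624961	
cg20754289	
cg20776526	
cg20827689	
cg20829258	
cg20854163	
cg20906389	
cg20946924	
cg21049597	
cg21153515	
cg21224238	
cg21236447	
cg21361093	
cg21388526	
cg21397795	
cg21469821	
cg21580044	
cg21713602	
cg21734827	
cg21790982	
cg21825213	
cg21874667	
cg21876629	
cg21937255	
cg22098054	
cg22131232	
cg22155779	
cg22181577	
cg22238831	
cg22297849	
cg22306396	
cg22374953	
cg22421825	
cg22424199	
cg22441608	
cg22449626	
cg22457448	
cg22589019	
cg22655646	
cg22693022	
cg22738771	
cg22742540	
cg22746028	
cg22819920	
cg22910935	
cg22936322	
cg22985597	
cg23029201	
cg23067621	
cg23081674	
cg23128658	
cg23136512	
cg23278150	
cg23285419	
cg23378134	
cg23389524	
cg23407071	
cg23461743	
cg23504995	
cg23532514	
cg23535181	
cg23540883	
cg23576582	
cg23613134	
cg23689474	
cg23703510	
cg23715670	
cg23720045	
cg23802639	
cg23811421	
cg23822466	
cg23853426	
cg23932525	
cg24019529	
cg24064602	
cg24102371	
cg24127670	
cg24182845	
cg24191836	
cg24215760	
cg24289255	
cg24349538	
cg24351182	
cg24362666	
cg24454315	
cg24502426	
cg24525421	
cg24534218	
cg24581134	
cg24702520	
cg24705445	
cg24705659	
cg24802025	
cg24826075	
cg24862595	
cg24929404	
cg24957230	
cg25014416	
cg25032579	
cg25076092	
cg25104284	
cg25151772	
cg25159265	
cg25218149	
cg25224488	
cg25268504	
cg25287065	
cg25314253	
cg25322268	
cg25399799	
cg25447892	
cg25520982	
cg25670229	
cg25674355	
cg25701127	
cg25791954	
cg25817121	
cg25902774	
cg25945259	
cg25967300	
cg25982515	
cg25987947	
cg26023348	
cg26044702	
cg26119321	
cg26180602	
cg26208823	
cg26285660	
cg26296264	
cg26316418	
cg26333289	
cg26384678	
cg26417925	
cg26446949	
cg26474609	
cg26693740	
cg26762136	
cg26825755	
cg26850088	
cg26853889	
cg26887123	
cg26903478	
cg26951733	
cg27014570	
cg27023017	
cg27090776	
cg27113067	
cg27208070	
cg27226222	
cg27264741	
cg27293203	
cg27295642	
cg27309567	
cg27383027	
cg27535171	
cg27668698	
cg27727190	
cg27736528	
cg27867774	
cg27872765	
cg27919315	
cg27979878	
cg28103158	
cg28119501	
cg28132331	
cg28163053	
cg28165258	
cg28173616	
cg28266160	
cg28266802	
cg28269827	
cg28274811	
cg28316483	
cg28362649	
cg28377609	
cg28401142	
cg28487323	
cg28545282	
cg28564078	
cg28565510	
cg28617993	
cg28666161	
cg28830151	
cg28953399	
cg28971704	
cg28976279	
cg29031666	
cg29065571	
cg29181972	
cg29215138	
cg29343551	
cg29361186	
cg29399902	
cg29432864	
cg29473157	
cg29526621	
cg29549671	
cg29662808	
cg29869203	
cg29870575	
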